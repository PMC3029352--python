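"""Domain types, configuration and tab-delimited I/O.

All expression values are log2(sample/control) ratios from a common-reference
two-colour design; linear fold ratios are ``2 ** mean(log2 ratio)``.  Sample
columns are labelled ``condition:replicate`` and conditions are validated
case-sensitively against a fixed panel registry.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Condition panels
# --------------------------------------------------------------------------

#: Seven nodule samples compared against nitrogen-starved control roots:
#: wild-type nodules at 4/10/14 dpi, nitrate-treated nodules (NN, 16 dpi) and
#: nodules induced by the exoA / bacA / fixJ rhizobial mutants (10 dpi).
NODULE_CONDITIONS: tuple[str, ...] = ("WT4", "WT10", "WT14", "NN", "exoA", "bacA", "fixJ")

#: Eight root samples for the qRT-PCR panel: purified Nod-factor treatment,
#: wild-type inoculation at 1 and 3 dpi, and five symbiotic mutants.
ROOT_CONDITIONS: tuple[str, ...] = ("NF", "WT1", "WT3", "nfp", "hcl1", "lin", "exoA", "efd1")

#: Control condition label (non-inoculated nitrogen-starved roots).
CONTROL = "CTRL"

PANELS: dict[str, tuple[str, ...]] = {
    "nodule": NODULE_CONDITIONS,
    "root": ROOT_CONDITIONS,
}

NA_TOKEN = "NA"
_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed table (duplicate probe ids, bad header, bad cell)."""


class PanelError(ValueError):
    """A condition name is not in the registered panel."""


class ReplicationError(ValueError):
    """A condition has fewer than two replicates."""


def panel_conditions(panel: str, with_control: bool = False) -> tuple[str, ...]:
    """Return the registered condition order for ``panel`` ('nodule'|'root')."""
    try:
        conds = PANELS[panel]
    except KeyError:
        raise PanelError(f"unknown panel {panel!r}; known: {sorted(PANELS)}") from None
    return conds + (CONTROL,) if with_control else conds


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds and conventions shared across the pipeline.

    Parameters
    ----------
    ratio_threshold:
        Minimum linear fold ratio (and 1/ratio for repression) for a
        differential call.  Inclusive.
    alpha:
        Benjamini-Hochberg adjusted-p threshold.  Inclusive.
    coexpr_threshold:
        Pearson r cut-off for co-expression neighbour queries.
    weak_fraction:
        An up-called condition whose linear ratio is below
        ``weak_fraction * max ratio`` of the probe counts as weak induction.
    most_samples_k:
        "Expressed in most samples" means up in WT4 plus at least this many
        of {WT10, WT14, bacA, fixJ} (NN is never considered).
    high_factor:
        qRT-PCR "++": the maximal fold must exceed ``high_factor`` times the
        next wild-type level.
    weak_vs_wt:
        qRT-PCR "+-": an induction below ``weak_vs_wt`` times the weakest
        wild-type inoculation fold.
    pooled_adjust:
        Apply BH across all condition contrasts pooled instead of per
        condition (default off; each condition is one contrast).
    """

    ratio_threshold: float = 1.5
    alpha: float = 0.05
    coexpr_threshold: float = 0.8
    weak_fraction: float = 0.5
    most_samples_k: int = 3
    high_factor: float = 2.0
    weak_vs_wt: float = 0.5
    min_agree_offset: int = 1
    pooled_adjust: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise ValueError("ratio_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.coexpr_threshold <= 1:
            raise ValueError("coexpr_threshold must be in [-1, 1]")
        if not 0 < self.weak_fraction <= 1:
            raise ValueError("weak_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# --------------------------------------------------------------------------
# ExpressionDataset
# --------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Probes x samples matrix of log2 ratios with condition/replicate labels.

    ``values`` has a probe-id index and a 2-level column MultiIndex
    ``(condition, replicate)``; ``annotations`` is an optional per-probe frame
    with columns ``family`` (str), ``is_regulator`` (bool), ``is_NCR`` (bool).
    """

    values: pd.DataFrame
    panel: str
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        cols = self.values.columns
        if cols.nlevels != 2:
            raise FormatError("columns must be (condition, replicate) pairs")
        allowed = set(panel_conditions(self.panel, with_control=True))
        conds = cols.get_level_values(0)
        bad = sorted(set(conds) - allowed)
        if bad:
            raise PanelError(f"conditions {bad} not in panel {self.panel!r}")
        counts = pd.Series(conds).value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ReplicationError(
                f"conditions with <2 replicates: {sorted(thin.index)}"
            )
        if self.values.isna().all(axis=1).any():
            raise FormatError("matrix has all-missing rows")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        """Conditions present, in registered panel order."""
        present = set(self.values.columns.get_level_values(0))
        return [c for c in panel_conditions(self.panel, with_control=True) if c in present]

    def replicates(self, condition: str) -> pd.DataFrame:
        """Replicate columns of one condition (probes x replicates)."""
        if condition not in set(self.values.columns.get_level_values(0)):
            raise PanelError(f"condition {condition!r} absent from dataset")
        return self.values[condition]

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean log2 ratio (probes x conditions)."""
        means = self.values.T.groupby(level=0).mean().T
        return means[self.conditions]


def _parse_sample_labels(labels: Sequence[str], panel: str) -> pd.MultiIndex:
    allowed = set(panel_conditions(panel, with_control=True))
    pairs = []
    for lab in labels:
        cond, sep, rep = lab.partition(":")
        if not sep or not rep:
            raise FormatError(f"sample label {lab!r} is not 'condition:replicate'")
        if cond not in allowed:
            raise PanelError(f"condition {cond!r} not in panel {panel!r}")
        try:
            rep_i = int(rep)
        except ValueError:
            raise FormatError(f"replicate index {rep!r} is not an integer") from None
        pairs.append((cond, rep_i))
    if len(set(pairs)) != len(pairs):
        raise FormatError("duplicate sample labels")
    return pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])


def read_expression_table(path: str | os.PathLike, panel: str) -> ExpressionDataset:
    """Read a tab-delimited probes x samples table of log2 ratios.

    First column holds probe ids, remaining headers are ``condition:replicate``.
    Missing cells are encoded ``NA``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids: {dups}")
    df.columns = _parse_sample_labels(list(df.columns), panel)
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = "probe"
    return ExpressionDataset(values=df, panel=panel)


def write_expression_table(dataset: ExpressionDataset, path: str | os.PathLike) -> None:
    """Write a dataset back to TSV, probes sorted ascending, panel-order columns."""
    df = dataset.values.copy()
    order = panel_conditions(dataset.panel, with_control=True)
    cols = sorted(df.columns, key=lambda c: (order.index(c[0]), c[1]))
    df = df.loc[sorted(df.index), cols]
    df.columns = [f"{c}:{r}" for c, r in df.columns]
    df.index.name = "probe"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe annotation table: probe, family, is_regulator, is_NCR."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        raise FormatError("duplicate probe ids in annotation table")
    for col in ("is_regulator", "is_NCR"):
        if col in df:
            df[col] = df[col].astype(bool)
    df.index = df.index.astype(str)
    return df


def write_annotations(annotations: pd.DataFrame, path: str | os.PathLike) -> None:
    ann = annotations.loc[sorted(annotations.index)].copy()
    for col in ("is_regulator", "is_NCR"):
        if col in ann:
            ann[col] = ann[col].astype(int)
    ann.index.name = "probe"
    ann.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# RegulationCallTable
# --------------------------------------------------------------------------

CALLS = ("up", "none", "down")


@dataclass
class RegulationCallTable:
    """Per probe x condition: call in {up, none, down}, mean linear ratio, p.

    All four frames share a probe index and condition columns.  ``flags``
    marks degenerate-variance ('degenerate') or untestable probes
    ('untestable'); empty string otherwise.
    """

    call: pd.DataFrame
    ratio: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                "", index=self.call.index, columns=self.call.columns
            )
        for frame in (self.ratio, self.p_raw, self.p_adj, self.flags):
            if not frame.index.equals(self.call.index) or not frame.columns.equals(
                self.call.columns
            ):
                raise FormatError("call-table frames are not aligned")
        bad = ~self.call.isin(CALLS)
        if bad.to_numpy().any():
            raise FormatError("calls must be one of up/none/down")

    @property
    def conditions(self) -> list[str]:
        return list(self.call.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.call.index)

    def de_probes(self) -> list[str]:
        """Probes with at least one non-none call."""
        mask = (self.call != "none").any(axis=1)
        return list(self.call.index[mask])

    def restrict(self, conditions: Sequence[str]) -> "RegulationCallTable":
        cols = list(conditions)
        return RegulationCallTable(
            call=self.call[cols],
            ratio=self.ratio[cols],
            p_raw=self.p_raw[cols],
            p_adj=self.p_adj[cols],
            flags=self.flags[cols],
        )


def write_calls(table: RegulationCallTable, path: str | os.PathLike) -> None:
    """Write a call table: probe, then per condition {call, ratio, p_adj}.

    Rows ordered by probe id ascending, conditions in table order; two writes
    of the same table are byte-identical.
    """
    probes = sorted(table.call.index)
    out = pd.DataFrame(index=pd.Index(probes, name="probe"))
    for cond in table.conditions:
        out[f"{cond}:call"] = table.call.loc[probes, cond]
        out[f"{cond}:ratio"] = table.ratio.loc[probes, cond]
        out[f"{cond}:p_adj"] = table.p_adj.loc[probes, cond]
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)


def read_calls(path: str | os.PathLike) -> RegulationCallTable:
    """Read a call table written by :func:`write_calls` (p_raw not persisted)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    conds: list[str] = []
    for col in df.columns:
        cond, sep, kind = col.rpartition(":")
        if not sep or kind not in {"call", "ratio", "p_adj"}:
            raise FormatError(f"unexpected calls column {col!r}")
        if cond not in conds:
            conds.append(cond)
    call = pd.DataFrame({c: df[f"{c}:call"] for c in conds})
    ratio = pd.DataFrame({c: pd.to_numeric(df[f"{c}:ratio"]) for c in conds})
    p_adj = pd.DataFrame({c: pd.to_numeric(df[f"{c}:p_adj"]) for c in conds})
    p_raw = pd.DataFrame(np.nan, index=call.index, columns=conds)
    return RegulationCallTable(call=call, ratio=ratio, p_raw=p_raw, p_adj=p_adj)


# --------------------------------------------------------------------------
# Ct tables (qRT-PCR)
# --------------------------------------------------------------------------


@dataclass
class CtTable:
    """qRT-PCR Ct values: genes x (condition, replicate), root panel + CTRL.

    ``reference`` names the constant-expression internal-standard gene
    (an ubiquitin gene in the source experiments); it must be a row.
    """

    values: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene ids in Ct table")
        if self.reference not in self.values.index:
            raise FormatError(f"reference gene {self.reference!r} absent")
        conds = set(self.values.columns.get_level_values(0))
        if CONTROL not in conds:
            raise FormatError("Ct table lacks CTRL (control root) samples")
        allowed = set(panel_conditions("root", with_control=True))
        bad = sorted(conds - allowed)
        if bad:
            raise PanelError(f"conditions {bad} not in root panel")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g in self.values.index if g != self.reference]

    @property
    def conditions(self) -> list[str]:
        present = set(self.values.columns.get_level_values(0))
        return [c for c in panel_conditions("root") if c in present]


def write_ct_table(table: CtTable, path: str | os.PathLike) -> None:
    df = table.values.copy()
    order = panel_conditions("root", with_control=True)
    cols = sorted(df.columns, key=lambda c: (order.index(c[0]), c[1]))
    genes = [table.reference] + sorted(g for g in df.index if g != table.reference)
    df = df.loc[genes, cols]
    flags = ["REF"] + [""] * (len(genes) - 1)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["flag"] = flags
    for c, r in cols:
        out[f"{c}:{r}"] = df[(c, r)].to_numpy()
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)


def read_ct_table(path: str | os.PathLike) -> CtTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    if "flag" not in df.columns:
        raise FormatError("Ct table lacks a 'flag' column (REF row marker)")
    refs = df.index[df["flag"] == "REF"].tolist()
    if len(refs) != 1:
        raise FormatError(f"expected exactly one REF row, found {len(refs)}")
    values = df.drop(columns="flag").astype(float)
    values.columns = _parse_sample_labels(list(values.columns), "root")
    return CtTable(values=values, reference=refs[0])


# --------------------------------------------------------------------------
# Class assignments & planted truth
# --------------------------------------------------------------------------


def write_assignment(assignment: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-probe class assignment (columns: label, argmax, levels)."""
    assignment.loc[sorted(assignment.index)].to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_assignment(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    return df


def write_truth(labels: pd.Series, path: str | os.PathLike) -> None:
    out = labels.loc[sorted(labels.index)].rename("label")
    out.index.name = "probe"
    out.to_csv(path, sep="\t")


def read_truth(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df["label"]
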