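"""qRT-PCR relative quantification and root activation/repression patterns.

Ct tables over eight root conditions (Nod-factor treatment, wild-type
inoculation at 1 and 3 dpi, and the nfp, hcl-1, lin, exoA, efd-1 symbiotic
mutants) plus control roots are converted to linear fold changes by the
2^-ddCt method against a constant reference gene (an ubiquitin gene in the
source experiments).  Per-condition symbols are then called:

``0``   not significant, or fold within (1/ratio_threshold, ratio_threshold)
``-``   significant repression (fold <= 1/ratio_threshold)
``++``  the condition attains the gene's maximum fold and that maximum is at
        least ``high_factor`` times the next wild-type level
``+-``  induction weaker than ``weak_vs_wt`` times the weakest significant
        wild-type inoculation fold
``+``   any other significant induction

Symbol vectors are finally matched against eight archetype templates,
four activated (A1-A4, ordered from pre-infection to infection-dependent
activation) and four repressed (R1-R4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model_io import (
    CONTROL,
    ROOT_CONDITIONS,
    AnalysisConfig,
    CtTable,
    ExpressionDataset,
    RegulationCallTable,
)
from .differential_expression import call_regulation

SYMBOLS = ("++", "+", "+-", "0", "-")

#: Wild-type situations (non-mutant backgrounds) used as induction references.
WT_SITUATIONS = ("NF", "WT1", "WT3")
#: Inoculated wild-type time points: the reference for "weaker than WT".
WT_INOCULATED = ("WT1", "WT3")

UNCLASSIFIED = "unclassified"

#: Allowed symbol sets per condition, exactly as printed in the pattern
#: definition table; composite slots like "+/++" become two-member sets.
ROOT_PATTERN_TEMPLATES: dict[str, dict[str, frozenset[str]]] = {
    "A1": {"NF": {"+"}, "WT1": {"+"}, "WT3": {"+", "++"}, "nfp": {"0"},
           "hcl1": {"+"}, "lin": {"+"}, "exoA": {"+"}, "efd1": {"+"}},
    "A2": {"NF": {"+"}, "WT1": {"+"}, "WT3": {"++"}, "nfp": {"0"},
           "hcl1": {"0"}, "lin": {"+"}, "exoA": {"0"}, "efd1": {"+"}},
    "A3": {"NF": {"0"}, "WT1": {"+"}, "WT3": {"++"}, "nfp": {"0"},
           "hcl1": {"0"}, "lin": {"+-"}, "exoA": {"+-"}, "efd1": {"+"}},
    "A4": {"NF": {"0"}, "WT1": {"+"}, "WT3": {"++"}, "nfp": {"0"},
           "hcl1": {"0"}, "lin": {"0"}, "exoA": {"0"}, "efd1": {"+", "+-"}},
    "R1": {"NF": {"-"}, "WT1": {"-"}, "WT3": {"-"}, "nfp": {"0"},
           "hcl1": {"-"}, "lin": {"-"}, "exoA": {"-"}, "efd1": {"-"}},
    "R2": {"NF": {"0"}, "WT1": {"-"}, "WT3": {"-"}, "nfp": {"0"},
           "hcl1": {"0"}, "lin": {"0"}, "exoA": {"0"}, "efd1": {"-"}},
    "R3": {"NF": {"-"}, "WT1": {"-"}, "WT3": {"-"}, "nfp": {"-"},
           "hcl1": {"-"}, "lin": {"0"}, "exoA": {"0"}, "efd1": {"-"}},
    "R4": {"NF": {"-"}, "WT1": {"-"}, "WT3": {"-"}, "nfp": {"-"},
           "hcl1": {"-"}, "lin": {"-"}, "exoA": {"-"}, "efd1": {"-"}},
}
ROOT_PATTERNS = tuple(ROOT_PATTERN_TEMPLATES)

_TEMPLATES = {
    pid: {c: frozenset(s) for c, s in tpl.items()}
    for pid, tpl in ROOT_PATTERN_TEMPLATES.items()
}


class MissingWTReferenceError(ValueError):
    """No significant wild-type inoculation fold to evaluate '+-' against."""


def relative_expression(
    ct_target, ct_reference, ct_target_control, ct_reference_control
):
    """Linear fold change by the 2^-ddCt method (100% efficiency).

    ddCt = (ct_target - ct_reference) - (ct_target_control -
    ct_reference_control); fold = 2^-ddCt.  Accepts scalars or arrays.
    """
    ddct = (np.asarray(ct_target) - np.asarray(ct_reference)) - (
        np.asarray(ct_target_control) - np.asarray(ct_reference_control)
    )
    fold = np.power(2.0, -ddct)
    return fold.item() if np.isscalar(ct_target) else fold


def call_symbols(
    folds: pd.Series, calls: pd.Series, config: AnalysisConfig | None = None
) -> pd.Series:
    """Call one gene's per-condition symbols from folds and up/none/down calls.

    ``calls`` carries the significance+threshold decision (same machinery as
    the array pipeline); ``folds`` are the mean linear fold changes.
    """
    config = config or AnalysisConfig()
    conds = list(folds.index)
    symbols = pd.Series("0", index=folds.index, dtype=object)
    symbols[calls == "down"] = "-"

    up = [c for c in conds if calls[c] == "up"]
    if not up:
        return symbols

    gmax = max(folds[c] for c in up)
    wt_up = [c for c in WT_INOCULATED if c in up]
    wt_ref = min(folds[c] for c in wt_up) if wt_up else None

    for c in up:
        next_wt = max(
            [folds[x] for x in WT_SITUATIONS if x in conds and x != c] + [1.0]
        )
        if folds[c] == gmax and gmax >= config.high_factor * next_wt:
            symbols[c] = "++"
            continue
        if wt_ref is None:
            if c in WT_SITUATIONS:
                symbols[c] = "+"
                continue
            raise MissingWTReferenceError(
                f"cannot grade induction at {c!r}: no significant "
                "wild-type inoculation reference"
            )
        symbols[c] = "+-" if folds[c] < config.weak_vs_wt * wt_ref else "+"
    return symbols


def match_pattern(symbols: pd.Series | dict[str, str]) -> str:
    """Return the matching pattern id, or ``unclassified``.

    A template matches when every condition's symbol lies in its allowed
    set; among several matches the most specific template (smallest total
    allowed-set size) wins, ties broken by the fixed A1..R4 order.
    """
    sym = dict(symbols)
    matches = []
    for pid in ROOT_PATTERNS:
        tpl = _TEMPLATES[pid]
        if all(sym.get(c) in tpl[c] for c in tpl):
            specificity = sum(len(tpl[c]) for c in tpl)
            matches.append((specificity, pid))
    if not matches:
        return UNCLASSIFIED
    matches.sort(key=lambda t: (t[0], ROOT_PATTERNS.index(t[1])))
    return matches[0][1]


def ct_to_log2_folds(ct_table: CtTable) -> ExpressionDataset:
    """Per-replicate log2 fold changes (-ddCt) for every gene and condition.

    Each replicate's dCt (target - reference) is compared with the mean
    control-root dCt of the same gene; the result is an expression dataset
    on the root panel suitable for the t/BH calling machinery.
    """
    values = ct_table.values
    ref = values.loc[ct_table.reference]
    genes = ct_table.gene_ids
    dct = values.loc[genes].sub(ref, axis=1)
    ctrl_mean = dct[CONTROL].mean(axis=1)
    conds = [c for c in ct_table.conditions]
    log2_folds = {}
    for cond in conds:
        block = dct[cond]
        for rep in block.columns:
            log2_folds[(cond, rep)] = -(block[rep] - ctrl_mean)
    mat = pd.DataFrame(log2_folds)
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=["condition", "replicate"])
    mat.index.name = "probe"
    return ExpressionDataset(values=mat, panel="root")


def classify_gene_panel(
    ct_table: CtTable, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, RegulationCallTable]:
    """Full root-pattern pipeline: Ct -> folds -> symbols -> pattern.

    Returns a per-gene frame with one symbol column per root condition plus
    a ``pattern`` column, and the underlying call table.
    """
    config = config or AnalysisConfig()
    dataset = ct_to_log2_folds(ct_table)
    calls = call_regulation(dataset, config)
    conds = [c for c in ROOT_CONDITIONS if c in calls.conditions]
    rows = {}
    for gene in calls.call.index:
        symbols = call_symbols(
            calls.ratio.loc[gene, conds], calls.call.loc[gene, conds], config
        )
        rows[gene] = {**symbols.to_dict(), "pattern": match_pattern(symbols)}
    result = pd.DataFrame.from_dict(rows, orient="index")[conds + ["pattern"]]
    result.index.name = "gene"
    return result, calls
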