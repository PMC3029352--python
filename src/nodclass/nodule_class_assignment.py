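"""Assignment of differentially regulated probes to nodule expression classes.

Every probe with at least one non-none call across the seven nodule
conditions receives exactly one class label.  Per-condition call levels are
first refined into four states — down, none, weak induction, maximal
induction — where "maximal" means an up call whose linear ratio reaches at
least ``weak_fraction`` of the probe's largest up ratio.  A fixed-precedence
rule list then maps the level vector (plus the argmax condition, i.e. the
condition of strongest expression) to one of 16 labels; probes mixing up and
down calls (down anywhere but NN) fall into the catch-all ``unclear`` class.

The per-class level templates used by the synthetic-data generator live here
too, so generator and classifier cannot drift apart; they also ship as a
versioned YAML data file (``data/class_templates.yaml``).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .data_model_io import (
    NODULE_CONDITIONS,
    AnalysisConfig,
    RegulationCallTable,
)

# Level alphabet
DOWN, NONE, WEAK, MAX = "down", "none", "weak", "max"
LEVELS = (DOWN, NONE, WEAK, MAX)
_LEVEL_CODE = {DOWN: "D", NONE: ".", WEAK: "w", MAX: "M"}

NOT_DE = "not_DE"

CLASS_LABELS = (
    "repressed",
    "zone1_2",
    "bacA",
    "fixJ",
    "diff1",
    "diff2",
    "fix_plus",
    "all_star",
    "all",
    "NN",
    "exo1",
    "exo2",
    "N4",
    "fix_plus_NN",
    "wt_nodules",
    "unclear",
)

#: One representative level vector per class, over the fixed condition order
#: (WT4, WT10, WT14, NN, exoA, bacA, fixJ).  These encode the published class
#: descriptions: e.g. zone1_2 = strongest expression in immature (4 dpi)
#: nodules and none in exoA nodules; diff1/diff2 = induced in 10 dpi and
#: older nodules, with/without bacA; exo2 = up exclusively in exoA nodules.
CLASS_TEMPLATES: dict[str, tuple[str, ...]] = {
    "repressed":   (DOWN, DOWN, DOWN, DOWN, DOWN, DOWN, DOWN),
    "zone1_2":     (MAX, WEAK, WEAK, NONE, NONE, WEAK, NONE),
    "bacA":        (WEAK, NONE, NONE, NONE, NONE, MAX, NONE),
    "fixJ":        (NONE, NONE, NONE, NONE, NONE, WEAK, MAX),
    "diff1":       (NONE, MAX, MAX, NONE, NONE, WEAK, MAX),
    "diff2":       (NONE, MAX, MAX, NONE, NONE, NONE, MAX),
    "fix_plus":    (NONE, MAX, MAX, DOWN, NONE, NONE, NONE),
    "all_star":    (WEAK, MAX, MAX, NONE, NONE, WEAK, WEAK),
    "all":         (WEAK, MAX, MAX, NONE, WEAK, WEAK, WEAK),
    "NN":          (NONE, WEAK, WEAK, MAX, NONE, NONE, NONE),
    "exo1":        (WEAK, WEAK, WEAK, NONE, MAX, WEAK, WEAK),
    "exo2":        (NONE, NONE, NONE, NONE, MAX, NONE, NONE),
    "N4":          (MAX, WEAK, WEAK, NONE, WEAK, NONE, NONE),
    "fix_plus_NN": (NONE, MAX, MAX, WEAK, NONE, NONE, NONE),
    "wt_nodules":  (WEAK, MAX, MAX, NONE, NONE, NONE, NONE),
    "unclear":     (MAX, NONE, NONE, NONE, NONE, DOWN, NONE),
}

#: Conditions counted for "expressed in most samples"; NN is never considered.
MOST_SAMPLES_SET = ("WT10", "WT14", "bacA", "fixJ")


def load_templates_yaml() -> dict[str, tuple[str, ...]]:
    """Read the shipped class-template YAML (same content as CLASS_TEMPLATES)."""
    text = resources.files("nodclass.data").joinpath("class_templates.yaml").read_text()
    raw = yaml.safe_load(text)
    return {label: tuple(levels) for label, levels in raw.items()}


def call_levels(
    calls: pd.Series, ratios: pd.Series, config: AnalysisConfig | None = None
) -> pd.Series:
    """Refine one probe's calls into down/none/weak/max levels.

    Among up calls, the largest mean linear ratio R_max defines "maximal
    induction": any up condition with ratio >= weak_fraction * R_max is max,
    the rest are weak.  A single up call is therefore always max.
    """
    config = config or AnalysisConfig()
    levels = pd.Series(NONE, index=calls.index, dtype=object)
    levels[calls == "down"] = DOWN
    up = calls == "up"
    if up.any():
        r_max = ratios[up].max()
        strong = up & (ratios >= config.weak_fraction * r_max)
        levels[up] = WEAK
        levels[strong] = MAX
    return levels


def _argmax_condition(levels: pd.Series, ratios: pd.Series | None) -> str | None:
    """Condition of strongest expression among up calls.

    With ratios available this is the largest mean linear ratio (ties broken
    by the fixed condition order); from levels alone it is the first
    max-level condition in the fixed order.
    """
    up_conds = [c for c in levels.index if levels[c] in (WEAK, MAX)]
    if not up_conds:
        return None
    if ratios is not None:
        best = max(up_conds, key=lambda c: (ratios[c], -levels.index.get_loc(c)))
        return best
    for c in levels.index:
        if levels[c] == MAX:
            return c
    return up_conds[0]


def classify_probe(
    levels: pd.Series,
    argmax: str | None = None,
    config: AnalysisConfig | None = None,
) -> str:
    """Map one level vector to its class label (first matching rule wins).

    ``levels`` is indexed by the seven nodule conditions.  ``argmax`` is the
    condition of strongest expression; if omitted it is derived from the
    levels (first max-level condition in fixed order).  A vector with no
    non-none entry returns ``not_DE``.
    """
    config = config or AnalysisConfig()
    up = {c for c in levels.index if levels[c] in (WEAK, MAX)}
    down = {c for c in levels.index if levels[c] == DOWN}

    if not up and not down:
        return NOT_DE
    if not up:
        return "repressed"                                   # (1)
    if down - {"NN"}:
        return "unclear"                                     # (2) mixed signs
    if argmax is None:
        argmax = _argmax_condition(levels, None)

    if up == {"exoA"}:
        return "exo2"                                        # (3)
    if argmax == "exoA":
        return "exo1"                                        # (4)
    if argmax == "WT4" and "exoA" not in up:
        return "zone1_2"                                     # (5)
    if argmax == "WT4" and "exoA" in up:
        return "N4"                                          # (6)
    if (
        "WT4" in up
        and len(up.intersection(MOST_SAMPLES_SET)) >= config.most_samples_k
        and argmax not in ("WT4", "exoA")
    ):
        return "all" if "exoA" in up else "all_star"         # (7)
    if argmax == "NN":
        return "NN"                                          # (8)
    if "WT4" not in up and ("WT10" in up or "WT14" in up) and "fixJ" in up:
        return "diff1" if "bacA" in up else "diff2"          # (9)
    if argmax == "bacA":
        return "bacA"                                        # (10)
    if argmax == "fixJ":
        return "fixJ"                                        # (11)
    if up <= {"WT10", "WT14"} and "NN" not in up:
        return "fix_plus"                                    # (12) NN may be down
    if ("WT10" in up or "WT14" in up) and "NN" in up and not up & {"exoA", "bacA", "fixJ"}:
        return "fix_plus_NN"                                 # (13)
    if up <= {"WT4", "WT10", "WT14", "NN"}:
        return "wt_nodules"                                  # (14)
    return "unclear"                                         # (15)


def classify_dataset(
    calls: RegulationCallTable, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Assign every probe one label; probes with no call become ``not_DE``.

    Returns a frame indexed by probe with columns ``label``, ``argmax`` and
    ``levels`` (compact string, e.g. ``"M.w..w."`` in the fixed condition
    order: M=max, w=weak, D=down, .=none).
    """
    config = config or AnalysisConfig()
    conds = [c for c in NODULE_CONDITIONS if c in calls.conditions]
    labels, argmaxes, level_strings = [], [], []
    call_f = calls.call[conds]
    ratio_f = calls.ratio[conds]
    for probe in call_f.index:
        levels = call_levels(call_f.loc[probe], ratio_f.loc[probe], config)
        argmax = _argmax_condition(levels, ratio_f.loc[probe])
        labels.append(classify_probe(levels, argmax, config))
        argmaxes.append(argmax if argmax is not None else "")
        level_strings.append("".join(_LEVEL_CODE[levels[c]] for c in conds))
    return pd.DataFrame(
        {"label": labels, "argmax": argmaxes, "levels": level_strings},
        index=call_f.index,
    )


def class_counts(assignment: pd.DataFrame) -> pd.Series:
    """Per-class probe counts over DE probes (``not_DE`` excluded)."""
    de = assignment[assignment["label"] != NOT_DE]
    counts = de["label"].value_counts()
    return counts.reindex(CLASS_LABELS, fill_value=0)
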