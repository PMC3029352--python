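"""Qualitative agreement of call patterns between two platforms.

Two call tables (e.g. two-colour oligo arrays vs an Affymetrix atlas) are
compared over their shared conditions after mapping probe ids.  A probe is
"qualitatively similar" when its call sign (up/none/down) agrees in at least
``min_agree`` of the shared conditions — by default all but one.  Probes
without a cross-platform mapping are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model_io import RegulationCallTable


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    fraction_pct: float
    verdicts: pd.Series
    discordant_detail: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_concordant": self.n_concordant,
            "fraction_pct": self.fraction_pct,
            "discordant_probes": sorted(self.verdicts.index[~self.verdicts]),
        }


def concordance(
    calls_a: RegulationCallTable,
    calls_b: RegulationCallTable,
    id_map: dict[str, str] | None = None,
    min_agree: int | None = None,
    shared_conditions: list[str] | None = None,
) -> ConcordanceReport:
    """Score per-probe qualitative agreement between two call tables.

    ``id_map`` maps probe ids of table a to ids of table b (identity if
    omitted); unmapped probes or probes absent from either table are
    skipped.  ``min_agree`` defaults to one fewer than the number of shared
    conditions.
    """
    if shared_conditions is None:
        shared = [c for c in calls_a.conditions if c in calls_b.conditions]
    else:
        shared = list(shared_conditions)
    if not shared:
        raise ValueError("no shared conditions to compare")
    if min_agree is None:
        min_agree = len(shared) - 1

    mapping = id_map if id_map is not None else {p: p for p in calls_a.probe_ids}
    a_call = calls_a.call[shared]
    b_call = calls_b.call[shared]

    verdicts = {}
    detail_rows = []
    for pa, pb in sorted(mapping.items()):
        if pa not in a_call.index or pb not in b_call.index:
            continue
        agree = (a_call.loc[pa] == b_call.loc[pb])
        ok = int(agree.sum()) >= min_agree
        verdicts[pa] = ok
        if not ok:
            for cond in shared:
                if not agree[cond]:
                    detail_rows.append(
                        {
                            "probe_a": pa,
                            "probe_b": pb,
                            "condition": cond,
                            "call_a": a_call.loc[pa, cond],
                            "call_b": b_call.loc[pb, cond],
                        }
                    )

    verdict_series = pd.Series(verdicts, dtype=bool)
    n_compared = len(verdict_series)
    n_concordant = int(verdict_series.sum())
    fraction = 100.0 * n_concordant / n_compared if n_compared else float("nan")
    detail = pd.DataFrame(
        detail_rows, columns=["probe_a", "probe_b", "condition", "call_a", "call_b"]
    )
    return ConcordanceReport(
        n_compared=n_compared,
        n_concordant=n_concordant,
        fraction_pct=fraction,
        verdicts=verdict_series,
        discordant_detail=detail,
    )


def single_condition_flag(calls: RegulationCallTable) -> pd.Series:
    """True for probes differentially expressed in exactly one condition."""
    return (calls.call != "none").sum(axis=1) == 1
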