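"""Input-inversion delta values and significant typological indicators.

Trained networks are probed by column inversion: for one technology at a
time, every assemblage's presence/absence bit for that technology is flipped
and the partially inverted table is fed back through the network. The delta
value is the change in a class probability, P_inverted − P_original.
Assemblages where the technology was originally present contribute to the
*removal* (presence → absence, "False Absence") condition; the rest to the
*addition* (absence → presence, "False Presence") condition.

Each trained network contributes one summary per technology × class ×
condition — the median delta over the applicable assemblages — and the
ensemble of per-network medians is treated as a bootstrap sampling
distribution of the median: its median is the reported effect and its 2.5th
and 97.5th percentiles form the 95% confidence interval.

A technology is a significant indicator (IND) of a class only under the dual
rule: the addition median is positive *and* the removal median negative,
neither CI covers zero, and both conditions rest on at least ``n_min = 10``
applicable assemblages. CONTRA is the sign-reversed case; everything else is
NS, with the failing rule components recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .assemblages import ClassScheme, TechnologyMatrix
from .ensemble import EnsembleResult
from .mlp import NetworkParameters, class_probabilities, rescale_inputs

REMOVAL = "removal"    # presence inverted to absence ("False Absence")
ADDITION = "addition"  # absence inverted to presence ("False Presence")

IND = "IND"
CONTRA = "CONTRA"
NS = "NS"


def invert_column(matrix: TechnologyMatrix, technology: str) -> TechnologyMatrix:
    """Flip one technology's column (0 ↔ 1) in a copy of the table."""
    j = matrix.technology_index(technology)
    out = matrix.copy()
    out.presence[:, j] = 1 - out.presence[:, j]
    return out


@dataclass
class DeltaRecord:
    """Aggregated delta values for one technology × class × condition."""

    technology: str
    class_name: str
    condition: str                      # REMOVAL or ADDITION
    per_network_medians: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n: int                              # applicable assemblages
    estimable: bool = True

    def ci_excludes_zero(self) -> bool:
        return self.estimable and (self.ci_low > 0.0 or self.ci_high < 0.0)


@dataclass
class IndicatorCall:
    """The {IND, CONTRA, NS} verdict for one technology × class."""

    technology: str
    class_name: str
    status: str
    reasons: dict = field(default_factory=dict)


def network_deltas(
    params: NetworkParameters,
    matrix: TechnologyMatrix,
    technology: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-assemblage, per-class deltas for one network and one technology.

    Returns ``(deltas, removal_mask)``: ``deltas[a, c]`` = P_inverted(c|a) −
    P_original(c|a) over the network's class-probability columns (two-way
    networks yield the (ΔP(LSA), −ΔP(LSA)) pair), and ``removal_mask[a]`` is
    True where the technology was originally present.
    """
    X = rescale_inputs(matrix.presence)
    X_inv = rescale_inputs(invert_column(matrix, technology).presence)
    deltas = class_probabilities(params, X_inv) - class_probabilities(params, X)
    removal_mask = matrix.column(technology).astype(bool)
    return deltas, removal_mask


def _percentiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and 2.5/97.5 percentiles, linear interpolation between order
    statistics (fixed so results are platform-reproducible)."""
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5], method="linear")
    return float(lo), float(med), float(hi)


def aggregate_deltas(
    per_network_medians: np.ndarray,
    technology: str,
    class_name: str,
    condition: str,
    n: int,
) -> DeltaRecord:
    """Build a DeltaRecord from the per-network median summaries.

    With ``n = 0`` (no assemblage in the condition) the record is flagged not
    estimable and carries NaN statistics.
    """
    values = np.asarray(per_network_medians, dtype=float)
    if n == 0 or values.size == 0 or np.isnan(values).all():
        return DeltaRecord(technology, class_name, condition,
                           np.array([]), np.nan, np.nan, np.nan, n, estimable=False)
    lo, med, hi = _percentiles(values)
    return DeltaRecord(technology, class_name, condition, values, med, lo, hi, n)


def compute_delta_records(
    ensemble: EnsembleResult,
    matrix: TechnologyMatrix,
    weighted: bool = False,
    pooled: bool = False,
) -> dict[tuple[str, str, str], DeltaRecord]:
    """All DeltaRecords for an ensemble: technology × class × condition.

    Default aggregation: each network contributes the median delta over the
    applicable assemblages, and percentiles are taken over those per-network
    medians. ``pooled=True`` instead pools all assemblage × network deltas
    (sensitivity mode). ``weighted=True`` weights networks by accuracy when
    taking the ensemble median (default unweighted).
    """
    scheme = ensemble.scheme
    X = rescale_inputs(matrix.presence)
    base = np.stack([class_probabilities(net.params, X) for net in ensemble.networks])
    records: dict[tuple[str, str, str], DeltaRecord] = {}
    acc = ensemble.accuracies()
    for technology in matrix.technologies:
        X_inv = rescale_inputs(invert_column(matrix, technology).presence)
        inv = np.stack(
            [class_probabilities(net.params, X_inv) for net in ensemble.networks]
        )
        deltas = inv - base                               # (W, n, K)
        removal_mask = matrix.column(technology).astype(bool)
        for condition, mask in ((REMOVAL, removal_mask), (ADDITION, ~removal_mask)):
            n = int(mask.sum())
            for c, class_name in enumerate(scheme.classes):
                if n == 0:
                    records[(technology, class_name, condition)] = aggregate_deltas(
                        np.array([]), technology, class_name, condition, 0
                    )
                    continue
                sub = deltas[:, mask, c]                  # (W, n)
                if pooled:
                    values = sub.ravel()
                else:
                    values = np.median(sub, axis=1)       # one median per network
                if weighted and not pooled:
                    values = _weighted_resample(values, acc)
                records[(technology, class_name, condition)] = aggregate_deltas(
                    values, technology, class_name, condition, n
                )
    return records


def _weighted_resample(values: np.ndarray, acc: np.ndarray) -> np.ndarray:
    """Expand per-network values proportionally to accuracy weights so the
    downstream percentile machinery sees an accuracy-weighted distribution."""
    w = np.asarray(acc, dtype=float)
    w = w / w.sum()
    reps = np.maximum(1, np.round(w * values.size * 10).astype(int))
    return np.repeat(values, reps)


def significance_call(
    removal: DeltaRecord,
    addition: DeltaRecord,
    n_min: int = 10,
) -> IndicatorCall:
    """Apply the dual-inversion significance rule to one technology × class."""
    if (removal.technology, removal.class_name) != (addition.technology, addition.class_name):
        raise ValueError("removal and addition records refer to different cells")
    reasons = {
        "removal_ci_excludes_zero": removal.ci_excludes_zero(),
        "addition_ci_excludes_zero": addition.ci_excludes_zero(),
        "removal_n_ok": removal.n >= n_min,
        "addition_n_ok": addition.n >= n_min,
        "opposite_signs": (
            removal.estimable and addition.estimable
            and removal.median * addition.median < 0
        ),
        "n_removal": removal.n,
        "n_addition": addition.n,
    }
    eligible = (
        reasons["removal_ci_excludes_zero"]
        and reasons["addition_ci_excludes_zero"]
        and reasons["removal_n_ok"]
        and reasons["addition_n_ok"]
        and reasons["opposite_signs"]
    )
    status = NS
    if eligible:
        if addition.median > 0 and removal.median < 0:
            status = IND
        elif addition.median < 0 and removal.median > 0:
            status = CONTRA
    return IndicatorCall(removal.technology, removal.class_name, status, reasons)


def extract_indicator_calls(
    records: dict[tuple[str, str, str], DeltaRecord],
    matrix: TechnologyMatrix,
    scheme: ClassScheme,
    n_min: int = 10,
) -> dict[tuple[str, str], IndicatorCall]:
    """Significance calls for every technology × class."""
    calls: dict[tuple[str, str], IndicatorCall] = {}
    for technology in matrix.technologies:
        for class_name in scheme.classes:
            calls[(technology, class_name)] = significance_call(
                records[(technology, class_name, REMOVAL)],
                records[(technology, class_name, ADDITION)],
                n_min=n_min,
            )
    return calls


def indicator_summary(
    calls: dict[tuple[str, str], IndicatorCall],
    scheme: ClassScheme,
) -> pd.DataFrame:
    """One row per technology with IND/CONTRA/blank per class; technologies
    with no significant call in any class are omitted."""
    rows = {}
    techs = sorted({t for (t, _c) in calls})
    for tech in techs:
        row = {}
        for cls in scheme.classes:
            call = calls.get((tech, cls))
            row[cls] = call.status if call and call.status != NS else ""
        if any(v for v in row.values()):
            rows[tech] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(scheme.classes))
    df.index.name = "Lithic component"
    return df


def indicator_sets(
    calls: dict[tuple[str, str], IndicatorCall],
    scheme: ClassScheme,
) -> dict[str, set[str]]:
    """Per-class sets of technologies called IND."""
    sets: dict[str, set[str]] = {cls: set() for cls in scheme.classes}
    for (tech, cls), call in calls.items():
        if call.status == IND:
            sets[cls].add(tech)
        elif call.status == CONTRA and len(scheme.classes) == 2:
            # two-way: a contra-indicator of LSA is an indicator of MSA and
            # vice versa (the two output probabilities are complementary)
            other = scheme.classes[1 - scheme.class_index(cls)]
            sets[other].add(tech)
    return sets


def delta_table(
    records: dict[tuple[str, str, str], DeltaRecord],
    calls: dict[tuple[str, str], IndicatorCall],
    class_name: str,
    technologies: list[str],
) -> pd.DataFrame:
    """Indicator-table layout for one class: lower/median/upper/n for both
    conditions plus the Sig and Ind/Contra columns, values to 3 decimals."""
    rows = []
    for tech in technologies:
        rem = records[(tech, class_name, REMOVAL)]
        add = records[(tech, class_name, ADDITION)]
        call = calls[(tech, class_name)]
        rows.append(
            {
                "Lithic component": tech,
                "FA Lower": round(rem.ci_low, 3) if rem.estimable else "",
                "FA Median": round(rem.median, 3) if rem.estimable else "",
                "FA Upper": round(rem.ci_high, 3) if rem.estimable else "",
                "FA n": rem.n,
                "FP Lower": round(add.ci_low, 3) if add.estimable else "",
                "FP Median": round(add.median, 3) if add.estimable else "",
                "FP Upper": round(add.ci_high, 3) if add.estimable else "",
                "FP n": add.n,
                "Sig": "SIG" if call.status != NS else "NS",
                "Ind / Contra": call.status if call.status != NS else "",
            }
        )
    return pd.DataFrame(rows)


def cross_class_overlap(
    matrix: TechnologyMatrix,
    sets_by_class: dict[str, set[str]],
) -> dict[str, Fraction]:
    """Proportions of assemblages containing indicators of multiple classes.

    An assemblage "contains indicators of class c" iff at least one
    technology in c's indicator set is present. Returns exact fractions for:
    ``multi_class`` (indicators of ≥2 classes), ``all_classes`` (indicators
    of every class), and for two-class schemes ``both_classes`` (an alias of
    ``all_classes``). Report as whole percents.
    """
    if not any(sets_by_class.values()):
        return {"multi_class": Fraction(0), "all_classes": Fraction(0),
                "both_classes": Fraction(0)}
    n = matrix.n_assemblages
    hits = np.zeros((n, len(sets_by_class)), dtype=bool)
    for k, (cls, techs) in enumerate(sets_by_class.items()):
        for tech in techs:
            hits[:, k] |= matrix.column(tech).astype(bool)
    n_classes_hit = hits.sum(axis=1)
    multi = Fraction(int((n_classes_hit >= 2).sum()), n)
    all_c = Fraction(int((n_classes_hit == len(sets_by_class)).sum()), n)
    out = {"multi_class": multi, "all_classes": all_c}
    if len(sets_by_class) == 2:
        out["both_classes"] = all_c
    return out


def condition_counts(matrix: TechnologyMatrix) -> pd.DataFrame:
    """Removal/addition sample sizes per technology (presence and absence
    counts; they always sum to the number of assemblages)."""
    rows = []
    for tech in matrix.technologies:
        present = int(matrix.column(tech).sum())
        rows.append({"technology": tech, "n_removal": present,
                     "n_addition": matrix.n_assemblages - present})
    return pd.DataFrame(rows)
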