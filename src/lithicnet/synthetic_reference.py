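"""A SYNTHETIC stand-in for the empirical 92 × 16 assemblage table.

The original presence/absence catalogue is distributed as supplementary
data and is not redistributed here. This module reconstructs a synthetic
surrogate from the summary statistics that *are* published:

* class sizes: 31 LSA, 31 MIS3&4 MSA, 30 MIS5 MSA;
* per-class prevalences for the seven technologies discussed individually
  (e.g. Backed Pieces 77/71/23% in LSA/MIS3&4/MIS5);
* the total number of assemblages containing each of the 16 technologies
  (the "False Absence" sample sizes of the indicator tables).

Per-class presence *counts* are fixed exactly: for the seven discussed
technologies the published per-class percentages round to counts that sum
precisely to the published totals (e.g. Backed Pieces 24 + 22 + 7 = 53);
the other nine technologies split their published total across classes in
proportion to class size (largest-remainder rounding), since no per-class
figures are published for them. Every marginal count in the surrogate is
therefore exact; only the within-class joint structure is invented.

Within a class, each technology's presences are assigned to a random
(seeded, fixed) subset of assemblages of exactly the required size,
independently across technologies — the same independence structure the
synthetic generator uses as its default null. The within-class joint
structure of the empirical table is not published, so analyses of joint
structure (pattern co-occurrence, classification accuracy, indicator
overlap percentages) on this surrogate approximate, and do not reproduce,
the empirical values.

One known inconsistency in the published summaries is preserved rather than
resolved: the indicator tables give Bipolar Tech a presence total of 62,
while the per-class prevalences (81/74/30%) imply 57. The surrogate follows
the per-class figures; see :func:`bipolar_presence_discrepancy`.
"""

from __future__ import annotations

import numpy as np

from .assemblages import CLASSES_3WAY, TECHNOLOGIES, TechnologyMatrix
from .synthetic import PUBLISHED_CLASS_SIZES, PUBLISHED_PREVALENCES

#: Published presence totals per technology (the removal-condition sample
#: sizes of the indicator tables).
PUBLISHED_PRESENCE_TOTALS: dict[str, int] = {
    "Backed Pieces": 53,
    "Bipolar Tech": 62,       # see bipolar_presence_discrepancy()
    "Blade Tech": 77,
    "Borer": 35,
    "Burin": 20,
    "Centripetal Tech": 54,
    "Core Tool": 23,
    "Denticulate": 10,
    "Levallois Blade Tech": 6,
    "Levallois Flake Tech": 55,
    "Levallois Point Tech": 14,
    "Notch": 40,
    "Platform Core": 45,
    "Point Tech": 58,
    "RT Bifacial": 16,
    "Scraper": 71,
}

#: Internal seed of the surrogate's membership draws. Part of the dataset's
#: definition: the surrogate is one fixed table, not a random sample.
_SURROGATE_SEED = 20200826


def per_class_presence_counts() -> dict[str, tuple[int, int, int]]:
    """Exact per-class presence counts used by the surrogate.

    Discussed technologies: published per-class percentages × class sizes,
    rounded half-up (these sums reproduce the published totals for all six
    cross-checkable technologies). Others: largest-remainder split of the
    published total proportional to class size.
    """
    sizes = np.array(PUBLISHED_CLASS_SIZES)
    counts: dict[str, tuple[int, int, int]] = {}
    for tech in TECHNOLOGIES:
        if tech in PUBLISHED_PREVALENCES:
            p = np.array(PUBLISHED_PREVALENCES[tech])
            counts[tech] = tuple(int(np.floor(pi * ni + 0.5)) for pi, ni in zip(p, sizes))
        else:
            total = PUBLISHED_PRESENCE_TOTALS[tech]
            exact = total * sizes / sizes.sum()
            base = np.floor(exact).astype(int)
            remainder = exact - base
            short = total - base.sum()
            order = np.argsort(-remainder)
            for k in range(short):
                base[order[k]] += 1
            counts[tech] = tuple(int(b) for b in base)
    return counts


def bipolar_presence_discrepancy() -> dict[str, int]:
    """The two irreconcilable published figures for Bipolar Tech presence:
    the indicator-table sample size (62) vs the count implied by the
    per-class prevalences (25 + 23 + 9 = 57). The surrogate uses 57."""
    implied = sum(per_class_presence_counts()["Bipolar Tech"])
    return {"inversion_table_n": PUBLISHED_PRESENCE_TOTALS["Bipolar Tech"],
            "class_prevalence_implied_n": implied}


def synthetic_reference_matrix() -> TechnologyMatrix:
    """Build the fixed synthetic surrogate table (92 assemblages × 16
    technologies, class sizes 31/31/30). Deterministic: repeated calls
    return identical tables."""
    rng = np.random.default_rng(_SURROGATE_SEED)
    counts = per_class_presence_counts()
    ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for c, (cls, size) in enumerate(zip(CLASSES_3WAY, PUBLISHED_CLASS_SIZES)):
        block = np.zeros((size, len(TECHNOLOGIES)), dtype=np.uint8)
        for j, tech in enumerate(TECHNOLOGIES):
            k = counts[tech][c]
            block[rng.permutation(size)[:k], j] = 1
        blocks.append(block)
        tag = {"LSA": "LSA", "MIS3&4 MSA": "MIS34", "MIS5 MSA": "MIS5"}[cls]
        ids.extend(f"SYNREF-{tag}-{i + 1:02d}" for i in range(size))
        labels.extend([cls] * size)
    return TechnologyMatrix(
        assemblage_ids=ids,
        technologies=list(TECHNOLOGIES),
        presence=np.vstack(blocks),
        labels3=labels,
    )
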