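"""Data model and I/O for binary typological assemblage tables.

The unit of analysis is the *assemblage*: the set of stone artefacts recovered
from one archaeological context. Each assemblage is described by the presence
(1) or absence (0) of 16 broad lithic technologies, and carries a class label
placing it in one of three groups spanning the Middle-to-Later Stone Age
transition in eastern Africa: LSA, MIS3&4 MSA, or MIS5 MSA (Marine Isotope
Stages 5 = 130-71 ka, 4 = 71-59 ka, 3 = 59-29 ka).

The canonical on-disk format is a headered CSV with columns
``assemblage_id, site, class3`` followed by the 16 technology columns in
alphabetical order. Missing values are rejected, never imputed: the
inversion-based indicator analysis counts assemblages per condition, and
silent imputation would corrupt those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

#: The 16 technology columns, in canonical (alphabetical) order.
TECHNOLOGIES: tuple[str, ...] = (
    "Backed Pieces",
    "Bipolar Tech",
    "Blade Tech",
    "Borer",
    "Burin",
    "Centripetal Tech",
    "Core Tool",
    "Denticulate",
    "Levallois Blade Tech",
    "Levallois Flake Tech",
    "Levallois Point Tech",
    "Notch",
    "Platform Core",
    "Point Tech",
    "RT Bifacial",
    "Scraper",
)

LSA = "LSA"
MIS34_MSA = "MIS3&4 MSA"
MIS5_MSA = "MIS5 MSA"
MSA = "MSA"

CLASSES_3WAY: tuple[str, ...] = (LSA, MIS34_MSA, MIS5_MSA)
CLASSES_2WAY: tuple[str, ...] = (LSA, MSA)

ID_COLUMN = "assemblage_id"
SITE_COLUMN = "site"
CLASS_COLUMN = "class3"

# Cell spellings accepted when parsing technology columns.
_PRESENT_TOKENS = {"1", "p", "present", "true", "yes"}
_ABSENT_TOKENS = {"0", "a", "absent", "false", "no"}


class AssemblageDataError(ValueError):
    """Raised for malformed or internally inconsistent assemblage tables."""


@dataclass(frozen=True)
class ClassScheme:
    """A classification scheme: either the two-way (LSA vs MSA) or the
    three-way (LSA vs MIS3&4 MSA vs MIS5 MSA) division of the data."""

    mode: str
    classes: tuple[str, ...]
    collapse_map: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def three_way() -> "ClassScheme":
        return ClassScheme(
            mode="three_way",
            classes=CLASSES_3WAY,
            collapse_map={c: c for c in CLASSES_3WAY},
        )

    @staticmethod
    def two_way() -> "ClassScheme":
        return ClassScheme(
            mode="two_way",
            classes=CLASSES_2WAY,
            collapse_map={LSA: LSA, MIS34_MSA: MSA, MIS5_MSA: MSA},
        )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def labels_for(self, labels3: list[str]) -> list[str]:
        """Map three-way labels into this scheme's label set."""
        try:
            return [self.collapse_map[lab] for lab in labels3]
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise AssemblageDataError(f"unknown class label: {exc.args[0]!r}") from exc

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


def scheme_from_name(name: str) -> ClassScheme:
    """Resolve ``"2way"``/``"3way"`` (and close variants) to a ClassScheme."""
    key = name.lower().replace("-", "").replace("_", "")
    if key in {"2way", "twoway", "2"}:
        return ClassScheme.two_way()
    if key in {"3way", "threeway", "3"}:
        return ClassScheme.three_way()
    raise AssemblageDataError(f"unknown scheme name: {name!r}")


@dataclass
class TechnologyMatrix:
    """A validated binary presence/absence table of assemblages × technologies.

    Attributes
    ----------
    assemblage_ids:
        Unique text labels, one per row.
    technologies:
        Ordered technology names (16 for the published dataset).
    presence:
        ``(n_assemblages, n_technologies)`` array of {0, 1}, dtype uint8.
    labels3:
        Per-assemblage three-way class label.
    sites:
        Optional site names (informational only).
    """

    assemblage_ids: list[str]
    technologies: list[str]
    presence: np.ndarray
    labels3: list[str]
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        n, t = self.presence.shape
        if len(self.assemblage_ids) != n:
            raise AssemblageDataError("assemblage_ids length does not match matrix rows")
        if len(self.technologies) != t:
            raise AssemblageDataError("technologies length does not match matrix columns")
        if len(self.labels3) != n:
            raise AssemblageDataError("labels3 length does not match matrix rows")
        dupes = _duplicates(self.assemblage_ids)
        if dupes:
            raise AssemblageDataError(f"duplicate assemblage ID: {dupes[0]!r}")
        if _duplicates(self.technologies):
            raise AssemblageDataError("technology names are not unique")
        vals = np.unique(self.presence)
        if not np.isin(vals, [0, 1]).all():
            raise AssemblageDataError(
                f"presence matrix contains non-binary values: {vals[~np.isin(vals, [0, 1])]}"
            )
        self.presence = self.presence.astype(np.uint8)
        unknown = set(self.labels3) - set(CLASSES_3WAY)
        if unknown:
            raise AssemblageDataError(f"unknown class label(s): {sorted(unknown)}")
        if self.sites is not None and len(self.sites) != n:
            raise AssemblageDataError("sites length does not match matrix rows")

    # ------------------------------------------------------------------ sizes
    @property
    def n_assemblages(self) -> int:
        return self.presence.shape[0]

    @property
    def n_technologies(self) -> int:
        return self.presence.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in CLASSES_3WAY}
        for lab in self.labels3:
            counts[lab] += 1
        return counts

    def technology_index(self, technology: str) -> int:
        try:
            return self.technologies.index(technology)
        except ValueError:
            raise AssemblageDataError(f"unknown technology: {technology!r}") from None

    def column(self, technology: str) -> np.ndarray:
        return self.presence[:, self.technology_index(technology)]

    # ------------------------------------------------------------- conversion
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                ID_COLUMN: self.assemblage_ids,
                SITE_COLUMN: self.sites if self.sites is not None else [""] * self.n_assemblages,
                CLASS_COLUMN: self.labels3,
            }
        )
        for j, tech in enumerate(self.technologies):
            df[tech] = self.presence[:, j].astype(int)
        return df

    def copy(self) -> "TechnologyMatrix":
        return TechnologyMatrix(
            assemblage_ids=list(self.assemblage_ids),
            technologies=list(self.technologies),
            presence=self.presence.copy(),
            labels3=list(self.labels3),
            sites=list(self.sites) if self.sites is not None else None,
        )


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it in seen:
            out.append(it)
        seen.add(it)
    return out


def _parse_cell(value, row_id: str, column: str) -> int:
    token = str(value).strip().lower()
    if token in _PRESENT_TOKENS:
        return 1
    if token in _ABSENT_TOKENS:
        return 0
    raise AssemblageDataError(
        f"unparseable presence/absence cell {value!r} at row {row_id!r}, column {column!r}"
    )


def read_assemblage_table(
    path: str | Path,
    dialect: str = "csv",
    require_16: bool = True,
) -> TechnologyMatrix:
    """Read a canonical assemblage CSV/TSV into a :class:`TechnologyMatrix`.

    The header must name an ID column, a class column, and the technology
    columns; an optional ``site`` column is carried through. Technology cells
    accept 1/0, P/A, present/absent, true/false, yes/no (case-insensitive).
    ``require_16=False`` permits other technology counts for synthetic
    experiments.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise AssemblageDataError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (ID_COLUMN, CLASS_COLUMN):
        if col not in df.columns:
            raise AssemblageDataError(f"missing required column {col!r} in {path}")
    tech_cols = [c for c in df.columns if c not in (ID_COLUMN, SITE_COLUMN, CLASS_COLUMN)]
    if require_16 and len(tech_cols) != 16:
        raise AssemblageDataError(
            f"expected 16 technology columns, found {len(tech_cols)} in {path}"
        )
    ids = [s.strip() for s in df[ID_COLUMN]]
    labels = [s.strip() for s in df[CLASS_COLUMN]]
    presence = np.empty((len(df), len(tech_cols)), dtype=np.uint8)
    for j, col in enumerate(tech_cols):
        for i, (val, row_id) in enumerate(zip(df[col], ids)):
            presence[i, j] = _parse_cell(val, row_id, col)
    sites = [s.strip() for s in df[SITE_COLUMN]] if SITE_COLUMN in df.columns else None
    return TechnologyMatrix(
        assemblage_ids=ids,
        technologies=tech_cols,
        presence=presence,
        labels3=labels,
        sites=sites,
    )


def write_assemblage_table(matrix: TechnologyMatrix, path: str | Path) -> None:
    """Write the canonical CSV (UTF-8, LF line endings)."""
    df = matrix.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def convert_xlsx(xlsx_path: str | Path, csv_path: str | Path, sheet: int | str = 0) -> TechnologyMatrix:
    """Convert a spreadsheet export of an assemblage table to canonical CSV.

    Expects the same header layout as the CSV contract; the CSV is the stable
    interface and the pipeline consumes only CSV.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet, dtype=str)
    tmp = Path(csv_path)
    with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")
    matrix = read_assemblage_table(tmp)
    write_assemblage_table(matrix, tmp)
    return matrix


def collapse_classes(labels3: list[str]) -> list[str]:
    """Collapse three-way labels to the two-way scheme (both MSA sub-classes → MSA)."""
    return ClassScheme.two_way().labels_for(list(labels3))


def prevalence(matrix: TechnologyMatrix, group: str = "ALL") -> dict[str, Fraction]:
    """Per-technology presence proportion, as exact fractions.

    ``group`` is a three-way class label or ``"ALL"``. Proportions are exact
    rationals (count present / group size); round only for reporting.
    """
    if group == "ALL":
        rows = np.ones(matrix.n_assemblages, dtype=bool)
    else:
        if group not in CLASSES_3WAY:
            raise AssemblageDataError(f"unknown group: {group!r}")
        rows = np.array([lab == group for lab in matrix.labels3])
        if not rows.any():
            raise AssemblageDataError(f"no assemblages with label {group!r}")
    denom = int(rows.sum())
    sub = matrix.presence[rows]
    return {
        tech: Fraction(int(sub[:, j].sum()), denom)
        for j, tech in enumerate(matrix.technologies)
    }


def presence_counts(matrix: TechnologyMatrix) -> dict[str, int]:
    """Number of assemblages in which each technology is present."""
    return {
        tech: int(matrix.presence[:, j].sum())
        for j, tech in enumerate(matrix.technologies)
    }
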