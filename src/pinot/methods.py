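"""Interaction-detection-method conversion.

Interaction databases annotate the assay behind each record with a PSI-MI
ontology code (``MI:nnnn``).  The same technique often appears under
several closely related codes — two-hybrid, two-hybrid array and
two-hybrid pooling are all yeast two-hybrid work — which would inflate a
naive count of "distinct methods".  A conversion table therefore reassigns
each code to a technique-family category; the Method Score later counts
categories, not raw codes.

Unmapped codes are a policy question: in lenient mode the bare code
becomes its own singleton category, in stringent mode the evidence
carrying it is dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

_CODE_RE = re.compile(r"MI:\d{4}")


class MethodTableError(ValueError):
    """Raised for a missing, malformed or self-contradictory table."""


@dataclass(frozen=True)
class MethodTable:
    """Mapping from PSI-MI detection code to method category label."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, category in self.mapping.items():
            if not _CODE_RE.fullmatch(code):
                raise MethodTableError(f"bad MI code {code!r}")
            if "\t" in category or ";" in category:
                raise MethodTableError(
                    f"category label {category!r} contains a reserved character"
                )

    @property
    def categories(self) -> list[str]:
        """Sorted category inventory (each label once)."""
        return sorted(set(self.mapping.values()))

    def __contains__(self, code: str) -> bool:
        return code in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def load_method_table(path: str | Path | None = None) -> MethodTable:
    """Load a two-column (code TAB category) conversion table.

    ``path=None`` loads the bundled table.  A code mapped to two different
    categories is a load error: the table is authoritative and must be
    unambiguous.
    """
    if path is None:
        ref = resources.files("pinot.data") / "method_table.tsv"
        with resources.as_file(ref) as p:
            return load_method_table(p)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise MethodTableError(f"malformed row at line {line_no}: {line!r}")
            code, category = parts[0].strip(), parts[1].strip()
            if code in mapping and mapping[code] != category:
                raise MethodTableError(
                    f"conflicting categories for {code}: "
                    f"{mapping[code]!r} vs {category!r}"
                )
            mapping[code] = category
    return MethodTable(mapping)


def convert_method(
    code: str, table: MethodTable, filter_mode: str = "lenient"
) -> str | None:
    """Reassign a detection code to its method category.

    Returns the category label, or — for a code absent from the table —
    the code itself as a singleton category in lenient mode and ``None``
    (discard) in stringent mode.  Pure function of its arguments.
    """
    if code in table.mapping:
        return table.mapping[code]
    if filter_mode == "lenient":
        return code
    if filter_mode == "stringent":
        return None
    raise ValueError(f"unknown filter mode {filter_mode!r}")


def coverage_report(codes, table: MethodTable) -> dict[str, int]:
    """Count occurrences of detection codes absent from the table.

    Utility for auditing a corpus before a stringent run: every code in
    ``codes`` is either in the table or reported here once with its count.
    """
    missing: dict[str, int] = {}
    for code in codes:
        if code not in table:
            missing[code] = missing.get(code, 0) + 1
    return missing
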