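"""Population Aggregation Analysis at the individual level.

A site diagnoses a focal group when the set of nucleotide states observed
across every individual of that group is disjoint from the union of states
observed in all other groups — a discontinuity in character variation, the
operational criterion for a phylogenetic-species lineage.  Two rules are
provided:

* ``attribute`` (default): disjointness of the focal state set from the
  union of the others.  A polymorphic site can still diagnose a group if
  none of its states leak into other groups.
* ``strict-fixed``: additionally requires the focal group to be fixed
  (a single state).

Morphological diagnosis by non-overlapping trait ranges (e.g. tooth counts
per hemimandible) is handled by :func:`range_diagnosis`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .containers import (VALID_BASES, CharacterMatrix, HaplotypeAlignment,
                         InputError)

DiagnosisMode = Literal["attribute", "strict-fixed"]


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic character: a site whose focal-group states are unique."""

    locus: str
    position: int
    group: str
    focal_states: frozenset
    other_states: frozenset


@dataclass
class DiagnosticReport:
    """Diagnostic sites found by PAA, sorted by locus then position."""

    entries: list[DiagnosticSite]
    mode: DiagnosisMode = "attribute"
    groups: tuple[str, ...] = ()
    loci: tuple[str, ...] = ()

    def counts(self) -> pd.DataFrame:
        """Per-group, per-locus diagnostic-site counts (0-filled)."""
        df = pd.DataFrame(0, index=list(self.groups), columns=list(self.loci),
                          dtype=int)
        for e in self.entries:
            df.loc[e.group, e.locus] += 1
        return df

    def count(self, group: str, locus: str | None = None) -> int:
        return sum(1 for e in self.entries
                   if e.group == group and (locus is None or e.locus == locus))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "locus": e.locus, "position": e.position, "group": e.group,
            "focal_states": "/".join(sorted(e.focal_states)),
            "other_states": "/".join(sorted(e.other_states)),
        } for e in self.entries])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "groups": list(self.groups),
            "loci": list(self.loci),
            "counts": {g: {l: int(self.counts().loc[g, l]) for l in self.loci}
                       for g in self.groups},
            "entries": [{
                "locus": e.locus, "position": e.position, "group": e.group,
                "focal_states": sorted(e.focal_states),
                "other_states": sorted(e.other_states)} for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def site_state_profile(alignment: HaplotypeAlignment,
                       positions: Sequence[int] | None = None,
                       locus: str = "locus") -> CharacterMatrix:
    """Collect per-group observed state sets at each (1-based) site.

    ``N`` and ``-`` contribute no state.  A site where any group ends up
    with an empty state set (only ambiguous data) is dropped globally, so
    that absence of data can never masquerade as a diagnostic difference.
    """
    groups = alignment.group_names()
    if not groups:
        raise InputError("empty alignment")
    by_group = alignment.by_group()
    if positions is None:
        positions = range(1, alignment.length + 1)
    cells: dict[int, dict[str, frozenset]] = {}
    for pos in positions:
        if not (1 <= pos <= alignment.length):
            raise InputError(f"position {pos} outside alignment (1..{alignment.length})")
        row: dict[str, frozenset] = {}
        for g in groups:
            states = frozenset(s[pos - 1] for s in by_group[g]) & VALID_BASES
            if not states:
                break
            row[g] = states
        else:
            cells[pos] = row
    return CharacterMatrix({locus: cells})


def find_diagnostic_sites(matrix: CharacterMatrix,
                          mode: DiagnosisMode = "attribute") -> DiagnosticReport:
    """Scan a character matrix for sites diagnostic of each group.

    attribute mode: site s diagnoses group g iff
    ``cell(g,s)`` is disjoint from the union of all other groups' cells.
    strict-fixed mode additionally requires ``|cell(g,s)| == 1``.
    """
    if mode not in ("attribute", "strict-fixed"):
        raise InputError(f"unknown mode {mode!r}")
    groups = matrix.groups()
    if len(groups) < 2:
        raise InputError("diagnosis requires >= 2 groups")
    entries: list[DiagnosticSite] = []
    for locus in matrix.loci:
        for pos in matrix.positions(locus):
            row = matrix.cells[locus][pos]
            for g in groups:
                others = frozenset().union(
                    *(row[h] for h in groups if h != g))
                focal = row[g]
                if focal & others:
                    continue
                if mode == "strict-fixed" and len(focal) != 1:
                    continue
                entries.append(DiagnosticSite(locus, pos, g, focal, others))
    entries.sort(key=lambda e: (e.locus, e.position, groups.index(e.group)))
    return DiagnosticReport(entries, mode, tuple(groups), tuple(matrix.loci))


def diagnostic_counts(report: DiagnosticReport) -> pd.DataFrame:
    """Per-group, per-locus counts table for a diagnostic report."""
    return report.counts()


# ---------------------------------------------------------------------------
# Morphological range diagnosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphRange:
    """Observed range of a morphometric trait in one group."""

    trait: str
    group: str
    min: float
    max: float
    n: int = 1
    units: str = ""

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise InputError(f"{self.trait}/{self.group}: min > max")
        if self.n < 1:
            raise InputError("sample count must be >= 1")


def range_diagnosis(a: MorphRange, b: MorphRange) -> str:
    """Compare two trait ranges: ``"disjoint"`` (diagnostic) or ``"overlapping"``.

    Ranges sharing even an endpoint overlap; only a gap between them is
    diagnostic.
    """
    if a.trait != b.trait:
        raise InputError(f"trait mismatch: {a.trait!r} vs {b.trait!r}")
    if a.units != b.units:
        raise InputError(f"unit mismatch: {a.units!r} vs {b.units!r}")
    return "disjoint" if (a.max < b.min or b.max < a.min) else "overlapping"
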