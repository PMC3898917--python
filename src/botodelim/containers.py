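"""Core in-memory containers shared across the analysis stages.

Three containers carry the data through the pipeline:

* :class:`HaplotypeAlignment` — an aligned set of mtDNA haplotypes, each
  tagged with a population/species label (the unit of the diagnostic-site
  and tree-based analyses).
* :class:`GenotypeTable` — a diploid multi-locus microsatellite genotype
  table (the unit of the clustering, ordination and QC analyses).
* :class:`CharacterMatrix` — per-group, per-site observed nucleotide state
  sets, the object on which individual-level Population Aggregation
  Analysis operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: sentinel for a missing allele call (STRUCTURE convention)
MISSING = -9

VALID_BASES = frozenset("ACGT")
#: symbols allowed in an alignment; N and - are treated as no-information
ALIGNMENT_ALPHABET = frozenset("ACGTN-")


class InputError(ValueError):
    """Raised when an input violates a precondition of an operation."""


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged data table fails its integrity checks."""


# ---------------------------------------------------------------------------
# HaplotypeAlignment
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Aligned haplotype sequences with per-sequence group labels.

    Sequences are stored upper-case over the alphabet ``{A,C,G,T,N,-}``;
    ``N`` and ``-`` carry no state information and are ignored by the
    diagnostic and distance computations.
    """

    ids: list[str]
    groups: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.groups) == len(self.sequences)):
            raise InputError("ids, groups and sequences must have equal length")
        if not self.sequences:
            raise InputError("alignment is empty")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InputError(f"sequences are not aligned: lengths {sorted(lengths)}")
        bad = set("".join(self.sequences)) - ALIGNMENT_ALPHABET
        if bad:
            raise InputError(f"invalid symbols in alignment: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def group_names(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def by_group(self) -> dict[str, list[str]]:
        """Map each group label to its member sequences."""
        out: dict[str, list[str]] = {}
        for g, s in zip(self.groups, self.sequences):
            out.setdefault(g, []).append(s)
        return out

    def subset(self, group: str) -> "HaplotypeAlignment":
        idx = [i for i, g in enumerate(self.groups) if g == group]
        if not idx:
            raise InputError(f"group {group!r} not present")
        return HaplotypeAlignment(
            [self.ids[i] for i in idx],
            [self.groups[i] for i in idx],
            [self.sequences[i] for i in idx],
        )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, fasta: str | Path,
                   label_map: str | Path | Mapping[str, str] | None = None
                   ) -> "HaplotypeAlignment":
        """Read a FASTA alignment.

        Group labels come either from an explicit ``label_map`` (a two-column
        TSV ``id<TAB>group`` or a mapping) or from record ids of the form
        ``group|individual``.
        """
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if not records:
            raise InputError(f"no sequences in {fasta}")
        mapping: Mapping[str, str] | None
        if label_map is None:
            mapping = None
        elif isinstance(label_map, Mapping):
            mapping = label_map
        else:
            df = pd.read_csv(label_map, sep="\t", header=None, dtype=str)
            mapping = dict(zip(df[0], df[1]))
        ids, groups, seqs = [], [], []
        for rec in records:
            ids.append(rec.id)
            if mapping is not None:
                if rec.id not in mapping:
                    raise InputError(f"id {rec.id!r} missing from label map")
                groups.append(mapping[rec.id])
            elif "|" in rec.id:
                groups.append(rec.id.split("|", 1)[0])
            else:
                raise InputError(
                    f"id {rec.id!r} has no 'group|individual' form and no label map given")
            seqs.append(str(rec.seq))
        return cls(ids, groups, seqs)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=i, description="")
                for i, s in zip(self.ids, self.sequences)]
        SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes with optional population labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; allele labels are
    positive integers (microsatellite fragment sizes or arbitrary codes) and
    missing calls hold :data:`MISSING`.
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise InputError("calls must have shape (n, n_loci, 2)")
        if self.calls.shape[0] != len(self.ids):
            raise InputError("calls rows != number of ids")
        if self.calls.shape[1] != len(self.loci):
            raise InputError("calls columns != number of loci")
        if self.groups is not None and len(self.groups) != len(self.ids):
            raise InputError("groups length != number of ids")
        present = self.calls[self.calls != MISSING]
        if present.size and present.min() <= 0:
            raise InputError("allele labels must be positive integers")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def group_names(self) -> list[str]:
        if self.groups is None:
            raise InputError("table carries no group labels")
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def subset(self, group: str) -> "GenotypeTable":
        if self.groups is None:
            raise InputError("table carries no group labels")
        idx = [i for i, g in enumerate(self.groups) if g == group]
        if not idx:
            raise InputError(f"group {group!r} not present")
        return GenotypeTable(
            [self.ids[i] for i in idx], list(self.loci),
            self.calls[idx], [self.groups[i] for i in idx])

    def locus_genotypes(self, locus: str) -> np.ndarray:
        """(n, 2) allele calls for one locus."""
        try:
            j = self.loci.index(locus)
        except ValueError:
            raise InputError(f"locus {locus!r} not present") from None
        return self.calls[:, j, :]

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"id": self.ids}
        cols["group"] = self.groups if self.groups is not None else [""] * self.n
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_1"] = self.calls[:, j, 0]
            cols[f"{locus}_2"] = self.calls[:, j, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, dtype={"id": str, "group": str})
        if "id" not in df.columns:
            raise InputError("genotype CSV must have an 'id' column")
        allele_cols = [c for c in df.columns if c.endswith("_1")]
        loci = [c[:-2] for c in allele_cols]
        calls = np.stack(
            [np.stack([df[f"{l}_1"].to_numpy(np.int64),
                       df[f"{l}_2"].to_numpy(np.int64)], axis=1) for l in loci],
            axis=1)
        groups = None
        if "group" in df.columns and not (df["group"].fillna("") == "").all():
            groups = df["group"].astype(str).tolist()
        return cls(df["id"].astype(str).tolist(), loci, calls, groups)

    def to_structure(self, path: str | Path) -> None:
        """Write the two-row-per-individual STRUCTURE text dialect.

        Columns: individual label, integer population code, one allele per
        locus; each individual occupies two consecutive rows.
        """
        names = self.group_names() if self.groups is not None else []
        code = {g: k + 1 for k, g in enumerate(names)}
        with open(path, "w") as fh:
            fh.write("\t".join(["id", "pop"] + list(self.loci)) + "\n")
            for i in range(self.n):
                pop = code[self.groups[i]] if self.groups is not None else 0
                for c in (0, 1):
                    row = [self.ids[i], str(pop)] + [
                        str(self.calls[i, j, c]) for j in range(self.n_loci)]
                    fh.write("\t".join(row) + "\n")

    @classmethod
    def from_structure(cls, path: str | Path) -> "GenotypeTable":
        with open(path) as fh:
            header = fh.readline().split()
            loci = header[2:]
            rows = [line.split() for line in fh if line.strip()]
        if len(rows) % 2:
            raise InputError("STRUCTURE file must have two rows per individual")
        ids, groups = [], []
        calls = np.empty((len(rows) // 2, len(loci), 2), dtype=np.int64)
        for i in range(0, len(rows), 2):
            r1, r2 = rows[i], rows[i + 1]
            if r1[0] != r2[0]:
                raise InputError(f"row pair mismatch at individual {r1[0]!r}")
            ids.append(r1[0])
            groups.append(r1[1])
            calls[i // 2, :, 0] = [int(x) for x in r1[2:]]
            calls[i // 2, :, 1] = [int(x) for x in r2[2:]]
        return cls(ids, loci, calls, groups)


# ---------------------------------------------------------------------------
# CharacterMatrix
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Per-group observed state sets at 1-based alignment positions.

    ``cells[locus][position][group]`` is a non-empty ``frozenset`` of
    nucleotide states drawn from ``{A,C,G,T}``.  This is the layout of the
    published diagnostic-character tables: one named locus partition, rows
    indexed by site position, one state-set column per species.
    """

    cells: dict[str, dict[int, dict[str, frozenset]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, sites in self.cells.items():
            for pos, row in sites.items():
                if pos < 1:
                    raise InputError(f"{locus}:{pos}: positions are 1-based")
                for g, states in row.items():
                    states = frozenset(states)
                    if not states or not states <= VALID_BASES:
                        raise InputError(
                            f"{locus}:{pos}:{g}: state set must be a non-empty "
                            f"subset of ACGT, got {set(states)}")
                    row[g] = states

    @property
    def loci(self) -> list[str]:
        return list(self.cells)

    def positions(self, locus: str) -> list[int]:
        return sorted(self.cells[locus])

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for sites in self.cells.values():
            for row in sites.values():
                for g in row:
                    seen.setdefault(g)
        return list(seen)

    def cell(self, locus: str, position: int, group: str) -> frozenset:
        return self.cells[locus][position][group]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, locus: str) -> "CharacterMatrix":
        """Read one locus partition from TSV (columns: position, one per group).

        Slash entries such as ``G/C`` denote a two-state set.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "position" not in df.columns:
            raise FixtureIntegrityError(f"{path}: no 'position' column")
        sites: dict[int, dict[str, frozenset]] = {}
        for _, row in df.iterrows():
            pos = int(row["position"])
            cell_row: dict[str, frozenset] = {}
            for g in df.columns[1:]:
                states = frozenset(str(row[g]).strip().upper().split("/"))
                if not states <= VALID_BASES or not states:
                    raise FixtureIntegrityError(
                        f"{path}: invalid state entry {row[g]!r} at site {pos}")
                cell_row[g] = states
            sites[pos] = cell_row
        return cls({locus: sites})

    def to_tsv(self, path: str | Path, locus: str) -> None:
        groups = self.groups()
        with open(path, "w") as fh:
            fh.write("\t".join(["position"] + groups) + "\n")
            for pos in self.positions(locus):
                row = self.cells[locus][pos]
                fh.write("\t".join(
                    [str(pos)] + ["/".join(sorted(row[g])) for g in groups]) + "\n")

    def merged(self, other: "CharacterMatrix") -> "CharacterMatrix":
        """Combine locus partitions from two matrices (disjoint locus names)."""
        overlap = set(self.cells) & set(other.cells)
        if overlap:
            raise InputError(f"duplicate locus partitions: {sorted(overlap)}")
        merged = dict(self.cells)
        merged.update(other.cells)
        return CharacterMatrix(merged)
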