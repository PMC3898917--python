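"""Packaged data tables.

Two published tables ship with the package as plain TSV:

* the model-support table for the admixture analysis — mean and standard
  deviation of LnP(K) over 20 replicate runs for K = 1..6 clusters of the
  121-individual, 10-locus *Inia* microsatellite data set;
* the three-species diagnostic-character matrices for the complete
  cytochrome *b* gene and the COI barcode region.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CharacterMatrix, FixtureIntegrityError

_DATA = resources.files("botodelim") / "data"


@dataclass(frozen=True)
class LnPTable:
    """Mean model support LnP(K) per candidate number of clusters K."""

    K: tuple[int, ...]
    repetitions: tuple[int, ...]
    mean_lnP: tuple[float, ...]
    stdev_lnP: tuple[float, ...]

    def __post_init__(self) -> None:
        ks = np.asarray(self.K)
        if len(ks) == 0 or np.any(np.diff(ks) <= 0):
            raise FixtureIntegrityError("K values must be strictly increasing")
        if any(r < 1 for r in self.repetitions):
            raise FixtureIntegrityError("repetitions must be >= 1")
        if not all(np.isfinite(self.mean_lnP)):
            raise FixtureIntegrityError("mean LnP values must be finite")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "K": self.K, "repetitions": self.repetitions,
            "mean_lnP": self.mean_lnP, "stdev_lnP": self.stdev_lnP})

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LnPTable":
        try:
            df = pd.read_csv(path, sep="\t")
            return cls(tuple(int(k) for k in df["K"]),
                       tuple(int(r) for r in df["repetitions"]),
                       tuple(float(x) for x in df["mean_lnP"]),
                       tuple(float(x) for x in df["stdev_lnP"]))
        except FixtureIntegrityError:
            raise
        except Exception as exc:  # malformed file -> integrity error
            raise FixtureIntegrityError(f"cannot parse LnP table {path}: {exc}") from exc


def load_table1() -> LnPTable:
    """Load the packaged LnP(K) model-support table (K = 1..6, 20 reps each)."""
    with resources.as_file(_DATA / "table1.tsv") as p:
        table = LnPTable.from_tsv(p)
    if table.K != (1, 2, 3, 4, 5, 6):
        raise FixtureIntegrityError("LnP table must cover K = 1..6")
    return table


#: species column names used in the packaged diagnostic-character matrices
SPECIES = ("araguaiaensis", "geoffrensis", "boliviensis")


def load_table2() -> CharacterMatrix:
    """Load the packaged diagnostic-character matrices.

    Returns a :class:`CharacterMatrix` with two locus partitions, ``cytb``
    (complete cytochrome *b*, 1-based gene coordinates) and ``coi``
    (barcode-region amplicon coordinates).  Slash entries in the printed
    table (states segregating within a species, e.g. ``G/C``) become
    two-state sets.
    """
    with resources.as_file(_DATA / "table2_cytb.tsv") as p:
        cytb = CharacterMatrix.from_tsv(p, "cytb")
    with resources.as_file(_DATA / "table2_coi.tsv") as p:
        coi = CharacterMatrix.from_tsv(p, "coi")
    matrix = cytb.merged(coi)
    if tuple(matrix.groups()) != SPECIES:
        raise FixtureIntegrityError(
            f"character matrix groups {matrix.groups()} != expected {SPECIES}")
    return matrix
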