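"""Allele frequencies from per-population genotype count tables.

Each row of a table gives, for one population, the number of individuals
homozygous for the ancestral allele, heterozygous, and homozygous for the
derived allele. Frequencies are plain allele counts over 2n chromosomes,
displayed to four decimals (half-up); raw fractions are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["GenotypeRow", "GenotypeTable", "allele_freqs", "population_summary", "round4"]


@dataclass(frozen=True)
class GenotypeRow:
    n_hom_ancestral: int
    n_het: int
    n_hom_derived: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ancestral, self.n_het, self.n_hom_derived) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ancestral + self.n_het + self.n_hom_derived


@dataclass
class GenotypeTable:
    rows: dict[str, GenotypeRow]

    def __post_init__(self) -> None:
        self.rows = {
            name: row if isinstance(row, GenotypeRow) else GenotypeRow(*row)
            for name, row in self.rows.items()
        }

    @property
    def totals(self) -> GenotypeRow:
        return GenotypeRow(
            sum(r.n_hom_ancestral for r in self.rows.values()),
            sum(r.n_het for r in self.rows.values()),
            sum(r.n_hom_derived for r in self.rows.values()),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeTable":
        return cls(
            {
                str(rec["population"]): GenotypeRow(
                    int(rec["hom_ancestral"]), int(rec["het"]), int(rec["hom_derived"])
                )
                for rec in frame.to_dict("records")
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": name,
                    "hom_ancestral": row.n_hom_ancestral,
                    "het": row.n_het,
                    "hom_derived": row.n_hom_derived,
                }
                for name, row in self.rows.items()
            ],
            columns=["population", "hom_ancestral", "het", "hom_derived"],
        )


def round4(x: float) -> float:
    """Half-up rounding to 4 decimals, the display convention."""
    return math.floor(x * 10**4 + 0.5) / 10**4


def allele_freqs(table: GenotypeTable, scope: str | None = None) -> tuple[float, float]:
    """Raw (unrounded) ancestral and derived allele frequencies for one
    population, or for the pooled table when ``scope`` is None."""
    row = table.totals if scope is None else table.rows[scope]
    if row.n == 0:
        raise ValueError(f"no individuals in scope {scope or 'total'!r}")
    freq_anc = (2 * row.n_hom_ancestral + row.n_het) / (2 * row.n)
    return freq_anc, 1.0 - freq_anc


def population_summary(table: GenotypeTable) -> pd.DataFrame:
    """One row per population plus a ``Total`` row of column sums, with
    display-rounded frequencies."""
    records = []
    for name, row in table.rows.items():
        fa, fd = allele_freqs(table, name) if row.n else (float("nan"), float("nan"))
        records.append(
            {
                "population": name,
                "n": row.n,
                "hom_ancestral": row.n_hom_ancestral,
                "het": row.n_het,
                "hom_derived": row.n_hom_derived,
                "freq_ancestral": round4(fa) if row.n else float("nan"),
                "freq_derived": round4(fd) if row.n else float("nan"),
            }
        )
    tot = table.totals
    fa, fd = allele_freqs(table)
    records.append(
        {
            "population": "Total",
            "n": tot.n,
            "hom_ancestral": tot.n_hom_ancestral,
            "het": tot.n_het,
            "hom_derived": tot.n_hom_derived,
            "freq_ancestral": round4(fa),
            "freq_derived": round4(fd),
        }
    )
    return pd.DataFrame(records)
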