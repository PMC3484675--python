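"""Bundled example data: a parent-gene/retrocopy variant ledger and a
per-population genotype count table from a published survey of a fixed
human retrocopy and its polymorphic parent gene. Used by the examples,
the acceptance checks, and as small realistic test inputs.
"""

from __future__ import annotations

from .gene_coords import Region, parse_coding_label
from .popfreq import GenotypeRow, GenotypeTable
from .varclass import SitePanel

__all__ = [
    "example_variant_ledger",
    "example_genotype_table",
    "reading_frame_positions",
]

# (coding position, parent alleles, retrocopy alleles); a slash separates
# the observed alleles at polymorphic sites, ancestral first
_LEDGER: list[tuple[str, str, str]] = [
    ("-135", "T", "T/C"),
    ("47", "C", "C/A"),
    ("126", "T", "T/C"),
    ("144", "G", "A"),
    ("165", "T/C", "T"),
    ("190", "G", "G/T"),
    ("246", "T/G", "T"),
    ("276", "G/A", "G"),
    ("363", "C/T", "C"),
    ("531", "C/T", "C"),
    ("552", "A", "A/T"),
    ("629", "C", "C/T"),
    ("754", "A", "A/C"),
    ("759", "G", "C"),
    ("798", "C/T", "C"),
    ("916", "=", "=/del"),  # 2-nt frameshifting deletion, polymorphic in the retrocopy
    ("*7", "G", "G/A"),
    ("*44", "G", "G/A"),
    ("*184", "repeat:12/repeat:15", "repeat:13/repeat:17"),
    ("*223", "repeat:17/repeat:19", "repeat:18/repeat:20"),
    ("*243", "G/A", "G"),
    ("*310", "T/C", "T"),
    ("*313", "C", "C/G"),
    ("*315", "C", "C/T"),
    ("*413", "G/A", "G"),
    ("*467", "G", "G/A"),
    ("*496", "T/del", "T"),
    ("*512", "G", "G/A"),
    ("*552", "=/del", "del"),  # 22-nt deletion, polymorphic in the parent only
    ("*606", "T", "G"),
    ("*663", "A/G", "A"),
    ("*802", "C/T", "C"),
    ("*843", "C/T", "C"),
    ("*875", "G/A", "A"),
    ("*910", "C/A", "C"),
    ("*956", "A/G", "A"),
]


def _panel(paralog: str, label: str, alleles: str) -> SitePanel:
    obs = {
        f"obs{i}": allele for i, allele in enumerate(alleles.split("/"), start=1)
    }
    return SitePanel(paralog, parse_coding_label(label), obs)


def example_variant_ledger() -> tuple[list[SitePanel], list[SitePanel]]:
    """The bundled variant ledger as (parent panels, retrocopy panels)."""
    parent = [_panel("parent", label, p) for label, p, _ in _LEDGER]
    retro = [_panel("retro", label, r) for label, _, r in _LEDGER]
    return parent, retro


def reading_frame_positions() -> set:
    """Positions of the ledger lying inside the reading frame."""
    return {
        parse_coding_label(label)
        for label, _, _ in _LEDGER
        if parse_coding_label(label).region is Region.CDS
    }


# population -> (hom ancestral, het, hom derived-deletion)
_GENOTYPES: dict[str, tuple[int, int, int]] = {
    "Africans South of the Sahara": (1, 6, 2),
    "Biaka Pygmy": (1, 2, 1),
    "Mbuti Pygmy": (2, 1, 2),
    "African-American": (2, 8, 4),
    "Druze": (5, 0, 0),
    "Indo-Pakistani": (3, 0, 0),
    "Russian Krasnodar": (2, 1, 0),
    "Ami": (0, 2, 3),
    "Chinese": (1, 4, 0),
    "Japanese": (0, 3, 1),
    "Southeast Asian": (0, 2, 1),
    "Pacific": (3, 1, 0),
    "South American": (4, 2, 1),
    "Mexican": (4, 4, 0),
    "Mexican-American": (2, 4, 3),
    "Puerto Rican": (1, 2, 5),
    "CEPH-Utah": (12, 10, 0),
    "Unidentified": (0, 1, 0),
}


def example_genotype_table() -> GenotypeTable:
    """Genotype counts for a segregating parent-allele deletion across 119
    individuals in 18 population samples."""
    return GenotypeTable({name: GenotypeRow(*row) for name, row in _GENOTYPES.items()})
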