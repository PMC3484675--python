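"""Truth-annotated synthetic data emulating a parent gene / retrocopy
system: a multi-exon parent gene, outgroup orthologs, a retrocopy of known
age inserted in reverse orientation into a host element with a target-site
duplication and poly(A) remnant, panel polymorphism in both paralogs, a
segregating parent-allele deletion, and short reads.

Substitutions follow a uniform (JC-like) model with an infinite-sites
guard: counts are Poisson(L * rate * time) and every planted event is
recorded in the :class:`TruthBundle`, recoverable independently of any
pipeline output. A fixed seed reproduces a bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_coords import CodingPosition, GeneModel, transcript_to_coding
from .paralog_reads import reverse_complement
from .varclass import SitePanel

__all__ = [
    "SimConfig",
    "TruthBundle",
    "SimRead",
    "simulate_history",
    "simulate_reads",
    "recovery_experiment",
    "save_bundle",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # gene anatomy
    n_exons: int = 4
    exon_len_range: tuple[int, int] = (180, 700)
    intron_len_range: tuple[int, int] = (300, 1200)
    utr5_len: int = 197
    utr3_len: int = 967
    # clock
    rate: float = 1.25e-9  # substitutions per site per year
    retro_age: float = 1.0e6  # years
    outgroup_times: tuple[tuple[str, float], ...] = (
        ("near_outgroup", 6.5e6),
        ("mid_outgroup", 9.0e6),
        ("far_outgroup", 14.0e6),
    )
    parent_branch_rate_factor: float = 0.0  # parent gene under purifying selection
    # insertion anatomy
    tsd_len: int = 15
    polya_len: int = 20
    host_element_len: int = 1500
    host_insertion_point: int = 700  # within the host element
    flank_len: int = 800
    # polymorphism
    n_poly_sites: int = 8  # per paralog
    maf_range: tuple[float, float] = (0.05, 0.45)
    panel_size: int = 20
    # segregating parent deletion (3' UTR)
    deletion_len: int = 22
    deletion_freq: float = 0.42
    # mononucleotide tract planted in the 3' UTR
    repeat_tract_len: int = 13
    repeat_retro_delta: int = -2
    # reads
    n_reads: int = 200
    read_len_range: tuple[int, int] = (36, 80)
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("need at least 2 exons")
        if self.retro_age >= min(t for _, t in self.outgroup_times):
            raise ValueError("retrocopy age must predate no outgroup divergence")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("minor-allele frequency range must lie in (0, 0.5)")
        if not 0 < self.deletion_freq < 1:
            raise ValueError("deletion frequency must lie in (0, 1)")
        if not 0 < self.host_insertion_point < self.host_element_len:
            raise ValueError("insertion point must fall inside the host element")
        if self.tsd_len > self.host_insertion_point:
            raise ValueError("TSD length exceeds host sequence 5' of the cut")


@dataclass(frozen=True)
class PlantedVariant:
    position: CodingPosition
    transcript_pos: int  # on the ancestral transcript, 1-based
    ancestral: str
    derived: str
    branch: str  # "retro" | "parent" | "parent_poly" | "retro_poly"
    frequency: float | None = None  # for segregating variants


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    origin: str
    start: int  # 0-based on the origin sequence
    strand: str  # "+" | "-"
    n_errors: int


@dataclass
class TruthBundle:
    config: SimConfig
    model: GeneModel  # the ancestral parent gene
    ancestor_transcript: str
    parent_primary_aligned: str  # equal-length rows; '-' marks the deletion
    parent_alternate_aligned: str
    outgroups: dict[str, str]  # spliced ortholog sequences
    retro_mrna: str  # derived retrocopy mRNA (deletion + fixed subs + tract delta)
    retro_locus: str
    element_interval: tuple[int, int]  # 0-based half-open on the locus
    tsd: str
    polya_len: int
    orientation: str
    fixed_variants: list[PlantedVariant]
    polymorphic_variants: list[PlantedVariant]
    parent_panels: list[SitePanel]
    retro_panels: list[SitePanel]
    deletion_transcript_start: int  # 1-based, inclusive
    repeat_tract_start: int  # 1-based on the ancestral transcript
    reads: list[SimRead] = field(default_factory=list)

    @property
    def true_age(self) -> float:
        return self.config.retro_age

    @property
    def retro_fixed_count(self) -> int:
        return sum(1 for v in self.fixed_variants if v.branch == "retro")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _draw_sites(
    rng: np.random.Generator, n: int, length: int, forbidden: set[int]
) -> list[int]:
    """Draw n distinct 1-based positions avoiding ``forbidden`` (the
    infinite-sites guard: collisions are re-drawn)."""
    sites: list[int] = []
    taken = set(forbidden)
    if length - len(taken) < n:
        raise ValueError("not enough free sites for the requested mutations")
    while len(sites) < n:
        p = int(rng.integers(1, length + 1))
        if p not in taken:
            taken.add(p)
            sites.append(p)
    return sites


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[int(rng.integers(0, 3))]


def simulate_history(cfg: SimConfig, with_panels: bool = True) -> TruthBundle:
    """Generate one full history under ``cfg`` (deterministic per seed).

    The ancestral gene is drawn uniformly; outgroup orthologs accumulate
    Poisson(L * rate * time) substitutions; the retrocopy is the spliced
    transcript of the deletion-bearing parent allele plus a poly(A) tail,
    reverse-complemented and inserted into the host element behind a
    target-site duplication; retrocopy (and optionally parent) lineages
    then accumulate their own substitutions for ``retro_age`` years.
    """
    rng = np.random.default_rng(cfg.seed)

    # -- ancestral gene ----------------------------------------------------
    min_spliced = cfg.utr5_len + cfg.utr3_len + 9
    for _ in range(100):  # redraw until the UTRs leave room for a frame
        exon_lens = [
            int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            for _ in range(cfg.n_exons)
        ]
        if sum(exon_lens) >= min_spliced:
            break
    else:
        raise ValueError("exon/UTR configuration leaves no room for a reading frame")
    intron_lens = [
        int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        for _ in range(cfg.n_exons - 1)
    ]
    spliced_len = sum(exon_lens)
    cds_start = cfg.utr5_len + 1
    cds_end = spliced_len - cfg.utr3_len
    cds_len = cds_end - cds_start + 1
    cds_end -= cds_len % 3  # keep the frame a multiple of 3

    genome_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    gpos = 0
    for i, el in enumerate(exon_lens):
        exons.append((gpos + 1, gpos + el))
        genome_parts.append(_random_seq(rng, el))
        gpos += el
        if i < len(intron_lens):
            il = intron_lens[i]
            # canonical-ish splice dinucleotides, cosmetic only
            genome_parts.append("GT" + _random_seq(rng, il - 4) + "AG")
            gpos += il
    sequence = "".join(genome_parts)

    # avoid a premature in-frame stop right at the start codon position:
    # force ATG at cds_start and a stop at the end of the frame so
    # protein-effect calls behave sensibly on synthetic models
    seq_list = list(sequence)
    model_tmp = GeneModel("ancestor", sequence, exons, cds_start, cds_end)
    start_g = model_tmp.transcript_to_genomic(cds_start)
    for k, b in enumerate("ATG"):
        seq_list[model_tmp.transcript_to_genomic(cds_start + k) - 1] = b
    for k, b in enumerate("TAA"):
        seq_list[model_tmp.transcript_to_genomic(cds_end - 2 + k) - 1] = b
    del start_g
    sequence = "".join(seq_list)

    # exon-exon junction windows stay untouched by every planted event so
    # that intron-loss evidence (junction 2k-mers) survives in the retrocopy
    junction_pad = 20
    junction_ts = np.cumsum(exon_lens)[:-1]  # junction after transcript pos jt
    junction_windows: set[int] = set()
    for jt in junction_ts:
        junction_windows.update(range(int(jt) - junction_pad, int(jt) + junction_pad + 1))

    def _clear_start(pref: int, length: int, spliced_len: int, busy: set[int]) -> int:
        """First start >= pref whose [start, start+length) avoids junction
        windows and ``busy``, staying inside the transcript."""
        s = pref
        while s + length - 1 <= spliced_len:
            span = set(range(s - 1, s + length + 1))
            if not (span & junction_windows) and not (span & busy):
                return s
            s += 1
        raise ValueError("no clear placement for a planted event in the 3' UTR")

    spliced_len_now = sum(exon_lens)
    tract_start_t = _clear_start(
        cds_end + cfg.utr3_len // 3, cfg.repeat_tract_len, spliced_len_now, set()
    )
    model_tmp2 = GeneModel("ancestor", sequence, exons, cds_start, cds_end)
    seq_list = list(sequence)
    for k in range(cfg.repeat_tract_len):
        seq_list[model_tmp2.transcript_to_genomic(tract_start_t + k) - 1] = "T"
    for t in (tract_start_t - 1, tract_start_t + cfg.repeat_tract_len):
        g = model_tmp2.transcript_to_genomic(t) - 1
        if seq_list[g] == "T":
            seq_list[g] = "C"
    sequence = "".join(seq_list)
    model = GeneModel("ancestor", sequence, exons, cds_start, cds_end)
    transcript = model.spliced_sequence
    L = len(transcript)

    # -- segregating parent deletion in the 3' UTR ------------------------
    tract = set(range(tract_start_t - 1, tract_start_t + cfg.repeat_tract_len + 1))
    del_start_t = _clear_start(
        cds_end + (2 * cfg.utr3_len) // 3, cfg.deletion_len, L, tract
    )
    del_end_t = del_start_t + cfg.deletion_len - 1
    deletion_region = set(range(del_start_t, del_end_t + 1))
    protected = (
        tract
        | deletion_region
        | junction_windows
        | set(range(cds_start, cds_start + 3))
        | set(range(cds_end - 2, cds_end + 1))
    )

    # -- outgroups ---------------------------------------------------------
    outgroups: dict[str, str] = {}
    outgroup_muts: dict[str, dict[int, str]] = {}
    for taxon, time in cfg.outgroup_times:
        n_mut = int(rng.poisson(L * cfg.rate * time))
        seq = list(transcript)
        muts: dict[int, str] = {}
        for p in _draw_sites(rng, n_mut, L, protected):
            seq[p - 1] = _mutate_base(rng, seq[p - 1])
            muts[p] = seq[p - 1]
        outgroups[taxon] = "".join(seq)
        outgroup_muts[taxon] = muts

    # -- lineage-specific fixed substitutions ------------------------------
    def planted_subs(n_mut: int, taken: set[int], branch: str) -> list[PlantedVariant]:
        out = []
        for p in _draw_sites(rng, n_mut, L, taken):
            taken.add(p)
            anc = transcript[p - 1]
            out.append(
                PlantedVariant(
                    transcript_to_coding(p, model), p, anc, _mutate_base(rng, anc), branch
                )
            )
        return out

    taken = set(protected)
    # substitutions accumulate over the compared sites: the retrocopy never
    # contained the deleted segment, and repeat-tract columns are excluded
    # from every comparison
    L_compared = L - cfg.deletion_len - cfg.repeat_tract_len
    n_retro = int(rng.poisson(L_compared * cfg.rate * cfg.retro_age))
    fixed = planted_subs(n_retro, taken, "retro")
    n_parent = int(
        rng.poisson(L_compared * cfg.rate * cfg.retro_age * cfg.parent_branch_rate_factor)
    )
    fixed += planted_subs(n_parent, taken, "parent")

    # -- panel polymorphism -------------------------------------------------
    poly: list[PlantedVariant] = []
    for branch in ("parent_poly", "retro_poly"):
        for p in _draw_sites(rng, cfg.n_poly_sites, L, taken):
            taken.add(p)
            anc = transcript[p - 1]
            freq = float(rng.uniform(*cfg.maf_range))
            poly.append(
                PlantedVariant(
                    transcript_to_coding(p, model), p, anc, _mutate_base(rng, anc),
                    branch, freq,
                )
            )

    # -- current sequences --------------------------------------------------
    parent_subs = {v.transcript_pos: v.derived for v in fixed if v.branch == "parent"}
    retro_subs = {v.transcript_pos: v.derived for v in fixed if v.branch == "retro"}

    parent_now = "".join(
        parent_subs.get(i + 1, transcript[i]) for i in range(L)
    )
    # primary reference carries the deletion (and one haplotype's derived
    # alleles); the alternate carries the other haplotype
    primary = list(parent_now)
    alternate = list(parent_now)
    for v in poly:
        if v.branch != "parent_poly":
            continue
        if rng.random() < 0.5:
            primary[v.transcript_pos - 1] = v.derived
        else:
            alternate[v.transcript_pos - 1] = v.derived
    for i in range(del_start_t - 1, del_end_t):
        primary[i] = "-"
    parent_primary_aligned = "".join(primary)
    parent_alternate_aligned = "".join(alternate)

    retro_chars = [
        retro_subs.get(i + 1, transcript[i]) for i in range(L)
    ]
    # retrocopy arose from the deletion-bearing parent allele
    retro_mrna_parts = []
    i = 0
    while i < L:
        if del_start_t <= i + 1 <= del_end_t:
            i += 1
            continue
        retro_mrna_parts.append(retro_chars[i])
        i += 1
    retro_mrna = "".join(retro_mrna_parts)
    if cfg.repeat_retro_delta:
        # shift the tract coordinates past the deletion if needed
        t0 = tract_start_t - 1
        if tract_start_t > del_end_t:
            t0 -= cfg.deletion_len
        run = cfg.repeat_tract_len + cfg.repeat_retro_delta
        retro_mrna = retro_mrna[:t0] + "T" * run + retro_mrna[t0 + cfg.repeat_tract_len :]

    # -- insertion into the host element ------------------------------------
    host = _random_seq(rng, cfg.host_element_len)
    flank5 = _random_seq(rng, cfg.flank_len)
    flank3 = _random_seq(rng, cfg.flank_len)
    p = cfg.host_insertion_point
    tsd = host[p - cfg.tsd_len : p]
    element = reverse_complement(retro_mrna + "A" * cfg.polya_len)
    left = flank5 + host[:p]
    locus = left + element + tsd + host[p:] + flank3
    element_interval = (len(left), len(left) + len(element))

    # -- observed panels -----------------------------------------------------
    parent_panels: list[SitePanel] = []
    retro_panels: list[SitePanel] = []
    if with_panels:
        n_ind = cfg.panel_size

        def sample_panel(anc: str, der: str, freq: float | None) -> dict[str, str]:
            if freq is None:
                return {f"ind{j}": der for j in range(n_ind)}
            draws = rng.random(n_ind) < freq
            return {
                f"ind{j}": (der if hit else anc) for j, hit in enumerate(draws)
            }

        for v in fixed:
            pos = v.position
            if v.branch == "retro":
                parent_panels.append(SitePanel("parent", pos, sample_panel(v.ancestral, v.ancestral, None)))
                retro_panels.append(SitePanel("retro", pos, sample_panel(v.ancestral, v.derived, None)))
            else:
                parent_panels.append(SitePanel("parent", pos, sample_panel(v.ancestral, v.derived, None)))
                retro_panels.append(SitePanel("retro", pos, sample_panel(v.ancestral, v.ancestral, None)))
        for v in poly:
            obs = sample_panel(v.ancestral, v.derived, v.frequency)
            mono = {f"ind{j}": v.ancestral for j in range(n_ind)}
            if v.branch == "parent_poly":
                parent_panels.append(SitePanel("parent", v.position, obs))
                retro_panels.append(SitePanel("retro", v.position, mono))
            else:
                retro_panels.append(SitePanel("retro", v.position, obs))
                parent_panels.append(SitePanel("parent", v.position, mono))
        # the segregating deletion: polymorphic in the parent, fixed in the
        # retrocopy (which descends from the deletion allele)
        del_pos = transcript_to_coding(del_start_t, model)
        parent_panels.append(
            SitePanel(
                "parent", del_pos,
                sample_panel("=", "del", cfg.deletion_freq),
            )
        )
        retro_panels.append(
            SitePanel("retro", del_pos, {f"ind{j}": "del" for j in range(n_ind)})
        )

    return TruthBundle(
        config=cfg,
        model=model,
        ancestor_transcript=transcript,
        parent_primary_aligned=parent_primary_aligned,
        parent_alternate_aligned=parent_alternate_aligned,
        outgroups=outgroups,
        retro_mrna=retro_mrna,
        retro_locus=locus,
        element_interval=element_interval,
        tsd=tsd,
        polya_len=cfg.polya_len,
        orientation="reverse",
        fixed_variants=fixed,
        polymorphic_variants=poly,
        parent_panels=parent_panels,
        retro_panels=retro_panels,
        deletion_transcript_start=del_start_t,
        repeat_tract_start=tract_start_t,
    )


def simulate_reads(
    bundle: TruthBundle,
    cfg: SimConfig | None = None,
    junction_targeted: bool = False,
    min_overhang: int = 10,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Sample short reads from the retrocopy locus and, as confounders,
    from the parent gene locus; per-base errors at the configured rate and
    every origin recorded.

    ``junction_targeted`` restricts retrocopy reads to placements covering
    at least ``min_overhang`` bases on each side of the element's 5'
    insertion boundary.
    """
    cfg = cfg or bundle.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    sources = {"retro_locus": bundle.retro_locus, "parent_locus": bundle.model.sequence}
    junction = bundle.element_interval[0]
    reads: list[SimRead] = []
    for i in range(cfg.n_reads):
        length = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
        if junction_targeted:
            origin = "retro_locus"
            lo = max(junction - length + min_overhang, 0)
            hi = min(junction - min_overhang, len(bundle.retro_locus) - length)
            if hi < lo:
                raise ValueError("read length too short for the requested overhang")
            start = int(rng.integers(lo, hi + 1))
        else:
            origin = "retro_locus" if rng.random() < 0.5 else "parent_locus"
            start = int(rng.integers(0, len(sources[origin]) - length + 1))
        seq = sources[origin][start : start + length]
        strand = "+"
        if rng.random() < 0.5:
            seq, strand = reverse_complement(seq), "-"
        n_err = 0
        if cfg.read_error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < cfg.read_error_rate:
                    chars[j] = _mutate_base(rng, chars[j])
                    n_err += 1
            seq = "".join(chars)
        reads.append(SimRead(f"read{i}", seq, origin, start, strand, n_err))
    bundle.reads = reads
    return reads


def recovery_experiment(
    cfg: SimConfig,
    replicates: int,
    rate_low: float | None = None,
    rate_high: float | None = None,
) -> pd.DataFrame:
    """Replicate simulate -> classify -> date and tabulate recovery of the
    true age: one row per replicate with the true age, the point estimate,
    the rate interval, and whether the interval covers the truth."""
    from .clock import RateModel, age_interval
    from .varclass import FixationStatus, classify_fixation, count_fixed_differences

    rate = RateModel(cfg.rate, rate_low or cfg.rate, rate_high or cfg.rate)
    rows = []
    for rep in range(replicates):
        rep_cfg = dataclasses.replace(cfg, seed=cfg.seed + rep)
        bundle = simulate_history(rep_cfg, with_panels=True)
        calls = classify_fixation(bundle.parent_panels, bundle.retro_panels)
        mask = comparison_mask(bundle)
        k, L = count_fixed_differences(calls, mask)
        est = age_interval(k, L, rate)
        rows.append(
            {
                "replicate": rep,
                "true_age": bundle.true_age,
                "k": k,
                "L": L,
                "point_age": est.point_age,
                "age_low": est.age_low,
                "age_high": est.age_high,
                "covered": est.age_low <= bundle.true_age <= est.age_high,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["bias"] = float((frame["point_age"] - frame["true_age"]).mean())
    frame.attrs["rmse"] = float(
        np.sqrt(((frame["point_age"] - frame["true_age"]) ** 2).mean())
    )
    frame.attrs["coverage"] = float(frame["covered"].mean())
    return frame


def comparison_mask(bundle: TruthBundle) -> set[CodingPosition]:
    """All transcript positions compared between the paralogs: everything
    except the deleted segment and the mononucleotide tract (indel and
    repeat columns are excluded from L by construction)."""
    cfg = bundle.config
    excluded = set(
        range(
            bundle.deletion_transcript_start,
            bundle.deletion_transcript_start + cfg.deletion_len,
        )
    ) | set(range(bundle.repeat_tract_start, bundle.repeat_tract_start + cfg.repeat_tract_len))
    return {
        transcript_to_coding(t, bundle.model)
        for t in range(1, len(bundle.ancestor_transcript) + 1)
        if t not in excluded
    }


# -- persistence ------------------------------------------------------------

def save_bundle(bundle: TruthBundle, outdir: str | Path) -> Path:
    """Write a bundle as plain-text files: FASTAs, TSV truth tables, a
    BED-style element sidecar, and the config snapshot."""
    from .io import write_fasta, write_tsv
    from .varclass import panels_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "parent_gene.fasta", {bundle.model.name: bundle.model.sequence})
    ann = pd.DataFrame(
        {
            "name": [bundle.model.name],
            "exons": [";".join(f"{s}-{e}" for s, e in bundle.model.exons)],
            "cds_start": [bundle.model.cds_start],
            "cds_end": [bundle.model.cds_end],
        }
    )
    write_tsv(outdir / "parent_gene.model.tsv", ann)
    write_fasta(
        outdir / "parent_references.fasta",
        {
            "parent_primary": bundle.parent_primary_aligned,
            "parent_alternate": bundle.parent_alternate_aligned,
        },
    )
    write_fasta(outdir / "outgroups.fasta", bundle.outgroups)
    write_fasta(outdir / "retro_locus.fasta", {"retro_locus": bundle.retro_locus})
    with open(outdir / "retro_element.bed", "w") as fh:
        fh.write(
            f"retro_locus\t{bundle.element_interval[0]}\t{bundle.element_interval[1]}\telement\n"
        )
    write_tsv(outdir / "panels.tsv", panels_to_frame(bundle.parent_panels + bundle.retro_panels))
    truth = pd.DataFrame(
        [
            {
                "position": str(v.position),
                "transcript_pos": v.transcript_pos,
                "ancestral": v.ancestral,
                "derived": v.derived,
                "branch": v.branch,
                "frequency": "" if v.frequency is None else v.frequency,
            }
            for v in bundle.fixed_variants + bundle.polymorphic_variants
        ]
    )
    write_tsv(outdir / "truth_variants.tsv", truth)
    if bundle.reads:
        write_fasta(outdir / "reads.fasta", {r.read_id: r.sequence for r in bundle.reads})
        write_tsv(
            outdir / "read_origins.tsv",
            pd.DataFrame(
                [
                    {
                        "read_id": r.read_id,
                        "origin": r.origin,
                        "start": r.start,
                        "strand": r.strand,
                        "n_errors": r.n_errors,
                    }
                    for r in bundle.reads
                ]
            ),
        )
    cfg_dict = dataclasses.asdict(bundle.config)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=list)
    meta = {
        "true_age": bundle.true_age,
        "tsd": bundle.tsd,
        "tsd_len": len(bundle.tsd),
        "polya_len": bundle.polya_len,
        "orientation": bundle.orientation,
        "element_interval": list(bundle.element_interval),
        "deletion_transcript_start": bundle.deletion_transcript_start,
        "repeat_tract_start": bundle.repeat_tract_start,
    }
    with open(outdir / "truth_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return outdir
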