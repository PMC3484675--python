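"""End-to-end pipeline: align, call and normalize variants, classify
fixation and polarity, reconstruct the parent allele, count fixed
differences, date the insertion, annotate its hallmarks, and (optionally)
screen short reads for junction-spanning evidence.

The pipeline consumes a bundle directory in the layout written by
:func:`retrodate.synthetic.save_bundle` and emits inspectable TSV
intermediates plus a JSON summary. It contains no randomness: a bundle
produced from a fixed seed yields bitwise-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .clock import (
    EnvelopePolicy,
    PresenceTable,
    RateModel,
    age_interval,
    presence_bounds,
    combine,
)
from .gene_coords import GeneModel, transcript_to_coding
from .pairalign import (
    VariantKind,
    call_variants,
    global_align,
    normalize_repeats,
)
from .paralog_reads import spans_junction
from .retro_features import (
    Orientation,
    detect_polya,
    detect_tsd,
    orientation_of,
    verify_intron_loss,
)
from .varclass import (
    assign_ancestral,
    calls_to_frame,
    classify_fixation,
    count_fixed_differences,
    panels_from_frame,
    reconstruct_parent,
)

log = logging.getLogger("retrodate")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_KNOWN_KEYS = {
    "rate", "presence", "envelope", "mask_L", "junction_min_overhang",
    "repeat_min_run", "intron_kmer", "tsd_max_len", "tsd_max_mismatch",
    "polya_window", "polya_min_len", "polya_min_purity", "seed", "verbose",
}


@dataclass
class PipelineConfig:
    """Thresholds and evidence external to the sequence data."""

    rate: RateModel = field(default_factory=lambda: RateModel(1.25e-9, 0.5e-9, 1.35e-9))
    presence: PresenceTable | None = None
    envelope: EnvelopePolicy = EnvelopePolicy.OUTER
    mask_L: int | None = None  # override the computed comparison length
    junction_min_overhang: int = 10
    repeat_min_run: int = 8
    intron_kmer: int = 18
    tsd_max_len: int = 30
    tsd_max_mismatch: int = 0
    polya_window: int = 50
    polya_min_len: int = 8
    polya_min_purity: float = 0.8
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "rate" in raw:
            r = raw["rate"]
            kwargs["rate"] = RateModel(
                float(r["point"]), float(r.get("low", r["point"])),
                float(r.get("high", r["point"])),
            )
        if "presence" in raw:
            kwargs["presence"] = PresenceTable(
                {
                    taxon: (spec["status"], (float(spec["low"]), float(spec["high"])))
                    for taxon, spec in raw["presence"].items()
                }
            )
        if "envelope" in raw:
            kwargs["envelope"] = EnvelopePolicy(raw["envelope"])
        for key in _KNOWN_KEYS - {"rate", "presence", "envelope"}:
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _load_inputs(bundle_dir: Path) -> dict:
    required = [
        "parent_gene.fasta", "parent_gene.model.tsv", "parent_references.fasta",
        "outgroups.fasta", "retro_locus.fasta", "retro_element.bed", "panels.tsv",
    ]
    missing = [f for f in required if not (bundle_dir / f).exists()]
    if missing:
        raise PipelineError("load", f"missing input files: {missing}")
    model = rio.read_gene_model(
        bundle_dir / "parent_gene.fasta", bundle_dir / "parent_gene.model.tsv"
    )
    refs = rio.read_fasta(bundle_dir / "parent_references.fasta")
    if len(refs) != 2:
        raise PipelineError("load", "parent_references.fasta must hold exactly 2 records")
    (primary_name, row_p), (alt_name, row_a) = list(refs.items())
    outgroups = rio.read_fasta(bundle_dir / "outgroups.fasta")
    locus = rio.read_fasta(bundle_dir / "retro_locus.fasta")["retro_locus"]
    bed = rio.read_bed(bundle_dir / "retro_element.bed")
    element_interval = (bed[0][1], bed[0][2])
    panels = panels_from_frame(rio.read_tsv(bundle_dir / "panels.tsv"))
    reads = None
    if (bundle_dir / "reads.fasta").exists():
        reads = rio.read_fasta(bundle_dir / "reads.fasta")
    return {
        "model": model,
        "row_p": row_p,
        "row_a": row_a,
        "primary_name": primary_name,
        "alt_name": alt_name,
        "outgroups": outgroups,
        "locus": locus,
        "element_interval": element_interval,
        "panels": panels,
        "reads": reads,
    }


def _polarize_references(model: GeneModel, row_p: str, row_a: str, outgroups: dict):
    """Ancestral calls at every substitution-discordant column of the two
    pre-aligned references; keyed by 1-based non-gap position on the
    primary row (the keying :func:`reconstruct_parent` expects)."""
    if len(row_p) != len(row_a):
        raise PipelineError("polarize", "reference rows must be pre-aligned (equal length)")
    calls: dict[int, object] = {}
    primary_pos = 0
    for c, (a, b) in enumerate(zip(row_p, row_a)):
        if a != "-":
            primary_pos += 1
        if a == "-" or b == "-" or a == b:
            continue
        og_states = {taxon: seq[c] if c < len(seq) else None for taxon, seq in outgroups.items()}
        pos = transcript_to_coding(c + 1, model)
        calls[primary_pos] = assign_ancestral(pos, {a, b}, og_states)
    return calls


def _mono_runs(seq: str, min_run: int) -> set[int]:
    """1-based positions inside mononucleotide runs of length >= min_run."""
    out: set[int] = set()
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] in "ACGT" and j - i >= min_run:
            out.update(range(i + 1, j + 1))
        i = j
    return out


def run_pipeline(
    bundle_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on a bundle directory and return the summary dict.

    When ``out_dir`` is given, intermediate TSVs and the summary JSON are
    written there (nothing is written on failure).
    """
    cfg = config or PipelineConfig()
    bundle_dir = Path(bundle_dir)
    if cfg.verbose:
        logging.basicConfig(level=logging.INFO)

    inputs = _load_inputs(bundle_dir)
    model: GeneModel = inputs["model"]
    transcript_len = model.spliced_length

    # -- parent-allele reconstruction ---------------------------------------
    anc_calls = _polarize_references(
        model, inputs["row_p"], inputs["row_a"], inputs["outgroups"]
    )
    recon = reconstruct_parent(inputs["row_p"], inputs["row_a"], anc_calls)
    merged_parent = recon.sequence
    # the deleted segment (gap in one reference) in full-transcript columns
    deletion_cols = {
        c + 1
        for c, (a, b) in enumerate(zip(inputs["row_p"], inputs["row_a"]))
        if (a == "-") != (b == "-")
    }
    log.info("merged parent: %d nt, %d ambiguous, %d excluded indel columns",
             len(merged_parent), recon.n_ambiguous, len(deletion_cols))

    # -- retrocopy feature annotation ---------------------------------------
    locus, interval = inputs["locus"], inputs["element_interval"]
    try:
        tsd_seq, tsd_len = detect_tsd(
            locus, interval, max_len=cfg.tsd_max_len, max_mismatch=cfg.tsd_max_mismatch
        )
    except ValueError as exc:
        raise PipelineError("features", str(exc)) from exc
    element = locus[interval[0] : interval[1]]
    orientation = orientation_of(element, merged_parent)
    oriented = element
    if orientation is Orientation.REVERSE:
        from .paralog_reads import reverse_complement

        oriented = reverse_complement(element)
    polya_len = detect_polya(
        oriented, cfg.polya_window, cfg.polya_min_len, cfg.polya_min_purity
    )
    junctions = verify_intron_loss(oriented, model, k=cfg.intron_kmer)
    retro_mrna = oriented.rstrip("A")  # drop the literal poly(A) remnant

    # -- variant extraction --------------------------------------------------
    # coordinates follow the full-length (non-deletion) frame; the merged
    # parent lacks the segregating deletion, so positions past it lift up
    merged_model = GeneModel(
        "merged_parent", merged_parent, [(1, len(merged_parent))],
        model.cds_start, model.cds_end,
    )
    aln = global_align(merged_parent, retro_mrna, names=("parent", "retrocopy"))
    variants = call_variants(aln, merged_model, polarity="a")
    variants = normalize_repeats(
        variants, aln, merged_model, min_run=cfg.repeat_min_run
    )
    del_before = sorted(deletion_cols)

    def lift(t_merged: int) -> int:
        t = t_merged
        for col in del_before:
            if col <= t:
                t += 1
            else:
                break
        return t

    var_rows = []
    for v in variants:
        full_pos = transcript_to_coding(lift(v.start_t), model)
        var_rows.append(
            {
                "label": f"{full_pos}{v.label[len(str(v.position)):]}",
                "region": full_pos.region.value,
                "position": str(full_pos),
                "kind": v.kind.value,
                "ancestral": v.ancestral,
                "derived": v.derived,
            }
        )
    variants_frame = pd.DataFrame(
        var_rows, columns=["label", "region", "position", "kind", "ancestral", "derived"]
    )

    # -- fixation classification and counting -------------------------------
    parent_panels = [p for p in inputs["panels"] if p.paralog == "parent"]
    retro_panels = [p for p in inputs["panels"] if p.paralog != "parent"]
    if not parent_panels or not retro_panels:
        raise PipelineError("classify", "panels.tsv must cover both paralogs")
    fix_calls = classify_fixation(parent_panels, retro_panels)

    excluded = set(deletion_cols)
    excluded |= _mono_runs(inputs["row_a"].replace("-", ""), cfg.repeat_min_run)
    for v in variants:
        if v.kind in (VariantKind.DELETION, VariantKind.INSERTION, VariantKind.REPEAT_LENGTH):
            excluded.update(range(lift(v.start_t), lift(max(v.end_t, v.start_t)) + 1))
    mask = {
        transcript_to_coding(t, model)
        for t in range(1, transcript_len + 1)
        if t not in excluded
    }
    k, L = count_fixed_differences(fix_calls, mask)
    if cfg.mask_L is not None:
        L = cfg.mask_L

    # -- dating ---------------------------------------------------------------
    estimate = age_interval(k, L, cfg.rate)
    bounds = presence_bounds(cfg.presence, cfg.envelope) if cfg.presence else None
    consensus = combine(estimate, bounds) if bounds else None

    # -- junction-spanning reads ---------------------------------------------
    junction_reads = []
    if inputs["reads"]:
        for rid, seq in inputs["reads"].items():
            placement = spans_junction(
                seq, locus, interval[0], min_overhang=cfg.junction_min_overhang
            )
            if placement.spans and placement.mismatches == 0:
                junction_reads.append(rid)

    summary = {
        "k": k,
        "L": L,
        "point_age_years": estimate.point_age,
        "point_age_my": estimate.point_my,
        "age_interval_years": [estimate.age_low, estimate.age_high],
        "age_interval_my": list(estimate.interval_my),
        "tsd": tsd_seq,
        "tsd_len": tsd_len,
        "polya_len": polya_len,
        "orientation": orientation.value,
        "introns_lost": [j.value for j in junctions],
        "n_variants": len(variants),
        "n_fixed_calls": sum(1 for c in fix_calls if c.status.value == "fixed_difference"),
        "n_ambiguous_reconstruction": recon.n_ambiguous,
        "n_junction_spanning_reads": len(junction_reads),
        "junction_spanning_reads": junction_reads,
    }
    if bounds:
        summary["presence_bounds_years"] = [bounds.lower, bounds.upper]
        summary["bounds_conflict"] = bounds.conflict
    if consensus:
        summary["consensus_interval_years"] = [consensus.low, consensus.high]
        summary["clock_vs_bounds_consistent"] = consensus.consistent

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rio.write_tsv(out_dir / "variants.tsv", variants_frame)
        rio.write_tsv(out_dir / "fixation_calls.tsv", calls_to_frame(fix_calls))
        rio.write_fasta(out_dir / "merged_parent.fasta", {"merged_parent": merged_parent})
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(out_dir / "summary.txt", "w") as fh:
            fh.write(_render_summary(summary))
    return summary


def _render_summary(s: dict) -> str:
    lines = [
        "retrocopy dating summary",
        "========================",
        f"fixed differences (k): {s['k']}",
        f"compared sites (L):    {s['L']}",
        f"point age:             {s['point_age_my']} My ({s['point_age_years']:.0f} years)",
        f"age interval:          {s['age_interval_my'][0]}-{s['age_interval_my'][1]} My",
        f"TSD:                   {s['tsd']} ({s['tsd_len']} nt)",
        f"poly(A) remnant:       {s['polya_len']} nt",
        f"orientation:           {s['orientation']}",
        f"introns:               {', '.join(s['introns_lost'])}",
    ]
    if "presence_bounds_years" in s:
        lo, hi = s["presence_bounds_years"]
        hi_txt = "open" if hi is None else f"{hi / 1e6:.2f} My"
        lines.append(f"presence bounds:       {lo / 1e6:.2f} My - {hi_txt}")
    if "consensus_interval_years" in s:
        lo, hi = s["consensus_interval_years"]
        lines.append(
            f"consensus interval:    {lo / 1e6:.2f}-{hi / 1e6:.2f} My "
            f"(consistent: {s['clock_vs_bounds_consistent']})"
        )
    if s.get("n_junction_spanning_reads"):
        lines.append(f"junction reads:        {s['n_junction_spanning_reads']}")
    return "\n".join(lines) + "\n"
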