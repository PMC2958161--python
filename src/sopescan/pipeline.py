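"""End-to-end orchestration: classify proteins, scan UTRs, call SOPEs, pool
logos, and integrate the gene-level call.

The pipeline is a pure composition of the module operations — every per-stage
output equals the corresponding operation run in isolation on the same
inputs, and the whole run is deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .seq_io import (
    NucleotideRecord,
    OrfAnnotation,
    ProteinRecord,
    Region,
    extract_utrs,
    find_orf,
    read_fasta,
    to_one_based,
    write_bed6,
)
from .box_models import BoxDefinition, default_box_set, scan_boxes
from .sope_caller import (
    ClusterParams,
    SopeCall,
    call_clusters,
    call_report_row,
    localize_sope,
)
from .protein_features import (
    ASH_CTERM_REFERENCE,
    AaClassConfig,
    integrate_gene_call,
    measure_protein,
)
from .conservation_logos import (
    InsufficientSitesError,
    SiteAlignment,
    build_pfm,
    flank_conservation_test,
    information_content,
    logo_table,
    sites_from_hits,
)

logger = logging.getLogger("sopescan")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs besides the two FASTA inputs."""

    box_defs: Sequence[BoxDefinition] = field(default_factory=default_box_set)
    cluster_params: ClusterParams = ClusterParams()
    cterm_min: float = 0.5
    cterm_reference: str = ASH_CTERM_REFERENCE
    search_tail: int = 40
    aa_classes: AaClassConfig = AaClassConfig()
    pairing: dict = field(default_factory=dict)  # protein id -> transcript id
    orf_table: dict = field(default_factory=dict)  # transcript id -> (start, end)
    out_dir: Optional[str] = None
    seed: int = 0
    scan_whole_transcript: bool = False
    logo_flank: int = 5
    n_perm: int = 1000


def _scan_transcript(
    record: NucleotideRecord, config: RunConfig
) -> tuple[Optional[OrfAnnotation], list, list]:
    """Scan a transcript's UTRs (or the whole sequence) and call clusters.

    Returns (orf, hits in transcript coordinates, localized SopeCalls).
    """
    provided = config.orf_table.get(record.id)
    orf = find_orf(
        record, Region(provided[0], provided[1]) if provided is not None else None
    )
    hits: list = []
    calls: list = []
    if config.scan_whole_transcript or orf is None:
        hits = scan_boxes(record.sequence, config.box_defs)
        calls = call_clusters(hits, config.cluster_params)
    else:
        five, three = extract_utrs(record, orf)
        for region in (five, three):
            if region is None or len(region) == 0:
                continue
            sub = record.sequence[region.start : region.end]
            sub_hits = [
                replace_hit(h, region.start) for h in scan_boxes(sub, config.box_defs)
            ]
            hits.extend(sub_hits)
            calls.extend(call_clusters(sub_hits, config.cluster_params))
    if orf is not None:
        calls = [
            c.with_location(localize_sope(c, orf, len(record))) for c in calls
        ]
    return orf, hits, calls


def replace_hit(hit, offset: int):
    """Shift a hit from sub-sequence to transcript coordinates."""
    from .box_models import BoxHit

    r = hit.region
    return BoxHit(
        hit.box_name,
        Region(r.start + offset, r.end + offset, r.strand),
        hit.strand,
        hit.matched_text,
    )


def _pooled_logos(
    per_gene_hits: dict, transcripts: dict, config: RunConfig
) -> dict:
    """Pool same-width site texts per box class across all genes and summarise."""
    out: dict = {}
    by_box: dict[str, list] = {}
    for t_id, hits in per_gene_hits.items():
        seq = transcripts[t_id].sequence
        for d in config.box_defs:
            if d.kind != "iupac_pattern":
                continue  # merged AT-rich regions have variable width
            box_hits = [h for h in hits if h.box_name == d.name]
            by_box.setdefault(d.name, []).extend(
                sites_from_hits(seq, box_hits, flank_len=config.logo_flank)
            )
    for name, sites in sorted(by_box.items()):
        if not sites:
            continue
        aln = SiteAlignment(box_name=name, sites=tuple(sites), flank_len=config.logo_flank)
        pfm = build_pfm(aln)
        track = information_content(pfm)
        core = slice(config.logo_flank, aln.width - config.logo_flank)
        entry = {
            "n_sites": pfm.n_sites,
            "consensus_core": track.consensus[core],
            "consensus_with_flanks": track.consensus,
            "total_ic_core_bits": round(float(track.ic[core].sum()), 6),
        }
        if config.logo_flank >= 1:
            try:
                ft = flank_conservation_test(
                    aln, n_perm=config.n_perm, seed=config.seed
                )
                entry["flank_mean_ic_bits"] = round(ft.observed_mean_ic, 6)
                entry["flank_p_value"] = round(ft.p_value, 6)
            except InsufficientSitesError:
                entry["flank_p_value"] = None
        out[name] = {"alignment": aln, "pfm": pfm, "track": track, "summary": entry}
    return out


def run_pipeline(
    transcripts: Union[str, Path, Sequence[NucleotideRecord]],
    proteins: Union[str, Path, Sequence[ProteinRecord]],
    config: RunConfig = RunConfig(),
) -> dict:
    """Run the whole analysis and return the machine-readable summary dict.

    When ``config.out_dir`` is set, also writes: box hits (BED6 + TSV), SOPE
    calls (BED6 + TSV), the per-protein report (TSV), pooled per-box logo
    tracks (TSV), ``summary.json`` and ``summary.txt``.  Byte-identical JSON
    for identical (inputs, config, seed).
    """
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts, alphabet="dna")
    if isinstance(proteins, (str, Path)):
        proteins = read_fasta(proteins, alphabet="protein")
    t_by_id = {r.id: r for r in transcripts}
    if not transcripts:
        logger.warning("no transcripts supplied; report will be empty")

    per_gene_hits: dict = {}
    per_gene_calls: dict = {}
    orfs: dict = {}
    for rec in transcripts:
        orf, hits, calls = _scan_transcript(rec, config)
        orfs[rec.id] = orf
        per_gene_hits[rec.id] = hits
        per_gene_calls[rec.id] = calls
        logger.info(
            "%s: %d box hits, %d cluster(s)", rec.id, len(hits), len(calls)
        )
        for h in hits:
            logger.debug(
                "hit %s %s [%d,%d) %s", rec.id, h.box_name, h.region.start,
                h.region.end, h.strand,
            )

    genes = []
    for prec in proteins:
        ev = measure_protein(
            prec.sequence,
            reference=config.cterm_reference,
            search_tail=config.search_tail,
            classes=config.aa_classes,
            cterm_min=config.cterm_min,
        )
        t_id = config.pairing.get(prec.id)
        if t_id is None or t_id not in t_by_id:
            if config.pairing:
                logger.warning(
                    "protein %s has no paired transcript; regulatory evidence "
                    "treated as absent", prec.id,
                )
            sope: Optional[SopeCall] = None
        else:
            calls = per_gene_calls.get(t_id, [])
            # the cluster nearest the ORF carries the regulatory evidence
            sope = calls[0] if calls else None
            if len(calls) > 1:
                sope = min(calls, key=lambda c: _orf_distance(c))
        gc = integrate_gene_call(ev, sope)
        entry = {
            "protein_id": prec.id,
            "transcript_id": t_id,
            "protein_label": ev.label,
            "gene_label": gc.gene_label,
            "ase_motif_hits": list(ev.ase_motif_hits),
        }
        if ev.cterm is not None:
            s1, e1 = to_one_based(ev.cterm.window)
            entry["cterm"] = {
                "window": [s1, e1],
                "identity": round(ev.cterm.identity, 6),
                "n_identical": ev.cterm.n_identical,
                "percent": ev.cterm.display_percent,
                "matched": ev.cterm.aligned_pair[1],
            }
        else:
            entry["cterm"] = None
        if sope is not None:
            entry["sope"] = call_report_row(sope, t_id or "")
        else:
            entry["sope"] = None
        genes.append(entry)

    logos = _pooled_logos(per_gene_hits, t_by_id, config)

    summary = {
        "sopescan_version": __version__,
        "seed": config.seed,
        "n_transcripts": len(transcripts),
        "n_proteins": len(list(proteins)),
        "cluster_params": {
            "gap_max": config.cluster_params.gap_max,
            "min_boxes": config.cluster_params.min_boxes,
            "min_types": config.cluster_params.min_types,
        },
        "genes": sorted(genes, key=lambda g: g["protein_id"]),
        "transcripts": {
            t_id: {
                "length": len(t_by_id[t_id]),
                "orf": list(
                    (orfs[t_id].orf.start, orfs[t_id].orf.end)
                )
                if orfs[t_id]
                else None,
                "n_hits": len(per_gene_hits[t_id]),
                "clusters": [
                    call_report_row(c, t_id) for c in per_gene_calls[t_id]
                ],
            }
            for t_id in sorted(t_by_id)
        },
        "logos": {name: v["summary"] for name, v in sorted(logos.items())},
    }

    if config.out_dir is not None:
        _write_outputs(
            Path(config.out_dir), summary, per_gene_hits, per_gene_calls, logos
        )
    return summary


def _orf_distance(call) -> int:
    loc = call.location
    if loc is None:
        return 0
    if loc.utr_side == "five_prime":
        return loc.upstream_distance
    if loc.utr_side == "three_prime":
        return loc.downstream_near
    return 0


def _write_outputs(out_dir, summary, per_gene_hits, per_gene_calls, logos) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    bed_rows, tsv_rows = [], []
    for t_id in sorted(per_gene_hits):
        for h in per_gene_hits[t_id]:
            bed_rows.append(
                (t_id, h.region.start, h.region.end, h.box_name, 0, h.strand)
            )
            tsv_rows.append(
                {
                    "sequence": t_id,
                    "box": h.box_name,
                    "start": h.region.start + 1,
                    "end": h.region.end,
                    "strand": h.strand,
                    "matched_text": h.matched_text,
                }
            )
    write_bed6(bed_rows, out_dir / "hits.bed")
    pd.DataFrame(
        tsv_rows,
        columns=["sequence", "box", "start", "end", "strand", "matched_text"],
    ).to_csv(out_dir / "hits.tsv", sep="\t", index=False)

    cluster_bed, cluster_rows = [], []
    for t_id in sorted(per_gene_calls):
        for c in per_gene_calls[t_id]:
            cluster_bed.append((t_id, c.region.start, c.region.end, "SOPE", 0, "+"))
            row = call_report_row(c, t_id)
            row["counts"] = json.dumps(row["counts"], sort_keys=True)
            cluster_rows.append(row)
    write_bed6(cluster_bed, out_dir / "clusters.bed")
    pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)

    protein_rows = []
    for g in summary["genes"]:
        row = {
            "protein_id": g["protein_id"],
            "transcript_id": g["transcript_id"],
            "protein_label": g["protein_label"],
            "gene_label": g["gene_label"],
            "ase_motif_hits": ",".join(str(p) for p in g["ase_motif_hits"]),
        }
        if g["cterm"]:
            row.update(
                cterm_identity=g["cterm"]["identity"],
                cterm_percent=g["cterm"]["percent"],
                cterm_window=f"{g['cterm']['window'][0]}-{g['cterm']['window'][1]}",
                cterm_matched=g["cterm"]["matched"],
            )
        protein_rows.append(row)
    pd.DataFrame(protein_rows).to_csv(out_dir / "proteins.tsv", sep="\t", index=False)

    logo_dir = out_dir / "logos"
    logo_dir.mkdir(exist_ok=True)
    for name, v in logos.items():
        logo_table(v["pfm"], v["track"]).to_csv(
            logo_dir / f"{name}.tsv", sep="\t", index=False
        )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(render_text_summary(summary))


def render_text_summary(summary: dict) -> str:
    """Human-readable digest of a run."""
    lines = [
        f"sopescan {summary['sopescan_version']} — "
        f"{summary['n_transcripts']} transcript(s), "
        f"{summary['n_proteins']} protein(s)",
        "",
    ]
    for g in summary["genes"]:
        lines.append(f"gene {g['protein_id']} (transcript {g['transcript_id']}):")
        if g["cterm"]:
            lines.append(
                f"  C-terminal domain identity {g['cterm']['percent']}% "
                f"({g['cterm']['n_identical']}/16)"
            )
        motif = g["ase_motif_hits"]
        lines.append(
            f"  Ase motif: {'present at ' + str(motif) if motif else 'absent'}"
        )
        lines.append(f"  protein label: {g['protein_label']}")
        if g["sope"]:
            s = g["sope"]
            lines.append(
                f"  SOPE: {s['span_bp']} bp, {s['n_boxes']} boxes "
                f"({s['counts']}), {s.get('location', '')}"
            )
        else:
            lines.append("  SOPE: none detected")
        lines.append(f"  gene label: {g['gene_label']}")
        lines.append("")
    for name, entry in summary["logos"].items():
        lines.append(
            f"{name}-box logo: n={entry['n_sites']}, "
            f"consensus {entry['consensus_core']}"
            + (
                f", flank p={entry['flank_p_value']}"
                if entry.get("flank_p_value") is not None
                else ""
            )
        )
    return "\n".join(lines) + "\n"
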