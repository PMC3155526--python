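"""Pipeline report bundle: table-shaped TSVs plus a JSON summary.

Annotation-only inputs (a feature table without a sequence) still produce
every coordinate-arithmetic report: layout, codon totals from gene lengths,
and genome length.  Sequence-bearing inputs add composition, codon usage,
start/stop and control-region reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import codon_usage_table, start_stop_report, total_codons_from_lengths
from .composition import composition_report, report_frame
from .genome_model import MitoGenome, extract_feature_sequence, read_fasta, read_feature_table, with_sequence
from .layout import adjacency_spacers, check_conservation, summarize_layout
from .structure_motifs import ScanParams, scan_control_region


@dataclass
class RunConfig:
    features: str | Path
    genome_fasta: str | Path | None = None
    genome_length: int | None = None
    out_dir: str | Path = "mitolens_report"
    genetic_code: int = 5
    scan_params: ScanParams = field(default_factory=ScanParams)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# mitolens {__version__} config={config.config_hash()} "
            f"seed={config.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def load_inputs(config: RunConfig) -> MitoGenome:
    genome = read_feature_table(config.features, genome_length=config.genome_length)
    if config.genome_fasta is not None:
        seq = read_fasta(config.genome_fasta)
        genome = with_sequence(genome, seq.sequence)
    return genome


def run_full_report(config: RunConfig) -> dict:
    """Run every applicable analysis; write TSVs and a summary JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = load_inputs(config)

    layout_report = adjacency_spacers(genome.features, genome.length)
    totals = summarize_layout(layout_report)
    _write_tsv(
        pd.DataFrame([a.__dict__ for a in layout_report.adjacencies]),
        out / "layout.tsv", config,
    )

    summary = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "genome": genome.name,
        "genome_length": genome.length,
        "n_features": len(genome.features),
        "total_intergenic": totals.total_intergenic,
        "n_intergenic_regions": totals.n_intergenic_regions,
        "total_overlap": totals.total_overlap,
        "n_overlap_locations": totals.n_overlap_locations,
        "longest_spacer": totals.longest_spacer,
        "longest_spacer_pair": totals.longest_spacer_pair,
        "length_conserved": check_conservation(totals),
        "total_codons_from_lengths": total_codons_from_lengths(genome.features),
    }

    if genome.sequence is not None:
        comp = composition_report(genome)
        _write_tsv(report_frame(comp), out / "composition.tsv", config)
        summary["at_content_pct"] = round(comp["Total"].at_content, 2)
        summary["at_skew"] = round(comp["Total"].at_skew, 3)
        summary["gc_skew"] = round(comp["Total"].gc_skew, 3)

        usage = codon_usage_table(genome)
        _write_tsv(usage.as_frame(), out / "codon.tsv", config)
        summary["total_codons"] = usage.total_codons

        ss = start_stop_report(genome)
        _write_tsv(
            pd.DataFrame([g.__dict__ for g in ss.genes]), out / "startstop.tsv", config
        )
        summary["start_codon_histogram"] = ss.start_histogram()
        summary["all_stops_complete"] = all(g.complete_stop for g in ss.genes)

        cr = [f for f in genome.features if f.feature_class == "noncoding"]
        if cr:
            region = extract_feature_sequence(genome, cr[0])
            cr_report = scan_control_region(region, config.scan_params)
            _write_tsv(
                pd.DataFrame(
                    [{"kind": h.kind, "start": h.start, "end": h.end, **h.detail}
                     for h in cr_report.hits]
                ),
                out / "control_region.tsv", config,
            )
            summary["control_region"] = {
                "name": cr[0].name,
                "length": cr[0].length,
                "at_content_pct": round(cr_report.at_content, 2),
                "n_element_hits": len(cr_report.hits),
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


__all__ = ["RunConfig", "run_full_report", "load_inputs"]
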