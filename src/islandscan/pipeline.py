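"""Pipeline configuration, end-to-end scan driver, and report assembly."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import __version__
from .genome import Direction, Genome, read_genome
from .homology import (HomologyHit, ScoringScheme, SearchThresholds,
                       ingest_tabular, search, write_hits_tsv)
from .irscan import IRParams, scan_upstream_all, write_ir_tsv
from .neighbourhood import (AssociationRecord, MarkerPanel, RegulatorLocus,
                            anchor_regulators, associate, class_distribution,
                            cooccurrence, percent, replicon_summary,
                            taxonomy_summary, write_associations_tsv,
                            write_cooccurrence_tsv, write_instances_tsv,
                            write_loci_tsv)

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Missing or unreadable pipeline input (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Scan parameters; defaults are the published analysis values."""

    window: int = 50_000
    upstream: int = 200
    evalue_primary: float = 1e-5
    evalue_sensitive: float = 1e-3
    min_arm: int = 20
    max_gap: int = 7
    max_mismatch: int = 2
    length_semantics: str = "per_arm"
    cluster_gap: int = 20_000
    direction_mode: str = "strand"
    genomes_dir: str = ""
    query: str = ""
    panel_fasta: str = ""
    panel_tsv: str = ""
    lineage: str = ""
    hits_tabular: str = ""  # precomputed 12-column homology results
    out_dir: str = "islandscan_out"
    seed: int = 0

    def ir_params(self) -> IRParams:
        return IRParams(min_arm=self.min_arm, max_gap=self.max_gap,
                        max_mismatch=self.max_mismatch,
                        length_semantics=self.length_semantics)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: type(getattr(cls(), f.name))
                 for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in types:
                    raise InputError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = types[key](value)
        return cls(**kwargs)


def load_genomes(genomes_dir: str | Path) -> list[Genome]:
    """Read all FASTA+GFF3 pairs (stem.fna/stem.gff3, or .fasta/.gff) and
    GenBank files (.gb/.gbk/.gbff) from a directory."""
    root = Path(genomes_dir)
    if not root.is_dir():
        raise InputError(f"genome directory not found: {root}")
    genomes = []
    fasta_exts = (".fna", ".fasta", ".fa")
    for fasta in sorted(p for p in root.iterdir()
                        if p.suffix in fasta_exts):
        gff = None
        for ext in (".gff3", ".gff"):
            cand = fasta.with_suffix(ext)
            if cand.exists():
                gff = cand
                break
        if gff is None:
            raise InputError(f"no GFF3 companion for {fasta}")
        protein = fasta.with_suffix(".faa")
        genomes.append(read_genome(
            fasta_path=fasta, gff3_path=gff,
            protein_fasta=protein if protein.exists() else None,
            assembly_id=fasta.stem))
    for gbk in sorted(p for p in root.iterdir()
                      if p.suffix in (".gb", ".gbk", ".gbff")):
        genomes.append(read_genome(genbank_path=gbk, assembly_id=gbk.stem))
    return genomes


@dataclass
class ScanResult:
    config: PipelineConfig
    genomes: list[Genome]
    regulator_hits: list[HomologyHit]
    marker_hits: list[HomologyHit]
    loci: list[RegulatorLocus]
    records: list[AssociationRecord]
    ir_per_locus: dict
    ir_summary: dict
    summary: dict
    manifest: dict


def summarize(records: Iterable[AssociationRecord],
              loci: Iterable[RegulatorLocus]) -> dict:
    """Headline numbers, every one recomputable from the detailed tables."""
    records, loci = list(records), list(loci)
    n_loci = len(loci)
    genome_loci: dict[str, int] = {}
    for locus in loci:
        genome_loci[locus.genome_id] = genome_loci.get(locus.genome_id, 0) + 1
    verdicts = {"downstream_only": 0, "upstream_only": 0, "both": 0, "none": 0}
    n_instances = n_marker_hits = 0
    for rec in records:
        verdicts[rec.verdict] += 1
        for inst in rec.systems_downstream + rec.systems_upstream:
            n_instances += 1
            n_marker_hits += len(inst.marker_hits)
    n_down_inst = sum(len(r.systems_downstream) for r in records)
    n_down_markers = sum(len(i.marker_hits)
                         for r in records for i in r.systems_downstream)
    associated = n_loci - verdicts["none"]
    downstream_assoc = verdicts["downstream_only"] + verdicts["both"]
    return {
        "n_loci": n_loci,
        "n_genomes": len(genome_loci),
        "n_multi_locus_genomes": sum(1 for v in genome_loci.values() if v > 1),
        "verdicts": verdicts,
        "n_associated": associated,
        "percent_associated": percent(associated, n_loci) if n_loci else 0.0,
        "n_downstream_associated": downstream_assoc,
        "percent_downstream_associated": (percent(downstream_assoc, n_loci)
                                          if n_loci else 0.0),
        "n_instances": n_instances,
        "n_marker_hits": n_marker_hits,
        "n_downstream_instances": n_down_inst,
        "n_downstream_marker_hits": n_down_markers,
    }


def run_scan(config: PipelineConfig,
             genomes: Optional[list[Genome]] = None,
             query: Optional[dict[str, str]] = None,
             panel: Optional[MarkerPanel] = None,
             lineage: Optional[dict] = None) -> ScanResult:
    """Execute homology -> anchoring -> windows -> grouping -> classification
    -> IR scan -> summaries, writing all TSVs plus a manifest.

    Inputs may be passed in memory; anything not supplied is loaded from the
    paths in ``config`` (missing paths raise :class:`InputError` before any
    computation).
    """
    # resolve inputs up front
    if genomes is None:
        genomes = load_genomes(config.genomes_dir)
    if query is None:
        if not config.query or not Path(config.query).exists():
            raise InputError(f"query FASTA not found: {config.query!r}")
        from Bio import SeqIO
        query = {rec.id: str(rec.seq)
                 for rec in SeqIO.parse(config.query, "fasta")}
    if panel is None:
        for path in (config.panel_fasta, config.panel_tsv):
            if not path or not Path(path).exists():
                raise InputError(f"panel file not found: {path!r}")
        panel = MarkerPanel.from_files(config.panel_fasta, config.panel_tsv)
    if lineage is None and config.lineage:
        if not Path(config.lineage).exists():
            raise InputError(f"lineage table not found: {config.lineage!r}")
        df = pd.read_csv(config.lineage, sep="\t")
        lineage = {
            row["assembly_id"]: {k: v for k, v in row.items()
                                 if k != "assembly_id" and isinstance(v, str)}
            for _, row in df.iterrows()
        }
    lineage = lineage or {}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = SearchThresholds(evalue_max=config.evalue_primary)
    scheme = ScoringScheme()

    # homology
    if config.hits_tabular:
        all_hits = ingest_tabular(config.hits_tabular, thresholds)
        reg_hits = [h for h in all_hits if h.query_id in query]
        marker_hits = [h for h in all_hits if h.query_id in panel]
    elif genomes:
        reg_hits = search(query, genomes, scheme, thresholds)
        marker_hits = search(panel.proteins(), genomes, scheme, thresholds)
    else:
        reg_hits, marker_hits = [], []
    log.info("homology: %d regulator hits, %d marker hits (E < %g)",
             len(reg_hits), len(marker_hits), thresholds.evalue_max)

    # anchoring and association
    loci = anchor_regulators(reg_hits, genomes, config.upstream)
    records = associate(loci, marker_hits, genomes,
                        window=config.window, cluster_gap=config.cluster_gap,
                        panel=panel, direction_mode=config.direction_mode)
    log.info("anchoring: %d hits -> %d loci -> %d associated",
             len(reg_hits), len(loci),
             sum(1 for r in records if r.verdict != "none"))

    # inverted repeats
    ir_per_locus, ir_summary = scan_upstream_all(loci, config.ir_params())

    # summaries
    summary = summarize(records, loci)
    summary["ir"] = ir_summary
    summary["replicon_types"] = replicon_summary(loci)

    # outputs
    write_hits_tsv(reg_hits, out / "regulator_hits.tsv")
    write_hits_tsv(marker_hits, out / "marker_hits.tsv")
    write_loci_tsv(loci, out / "loci.tsv")
    write_instances_tsv(records, out / "instances.tsv")
    write_associations_tsv(records, out / "associations.tsv")
    write_cooccurrence_tsv(cooccurrence(records), out / "cooccurrence.tsv")
    class_distribution(records).to_csv(out / "class_distribution.tsv",
                                       sep="\t", index=False)
    taxonomy_summary(loci, lineage).to_csv(out / "taxonomy.tsv",
                                           sep="\t", index=False)
    all_irs = [r for reps in ir_per_locus.values() for r in reps]
    write_ir_tsv(all_irs, out / "inverted_repeats.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    manifest = {
        "tool": "islandscan",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": {
            "genomes_scanned": len(genomes),
            "regulator_hits": len(reg_hits),
            "marker_hits": len(marker_hits),
            "loci": len(loci),
            "associated_loci": summary["n_associated"],
            "instances": summary["n_instances"],
            "inverted_repeats": ir_summary["n_irs"],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ScanResult(config=config, genomes=genomes,
                      regulator_hits=reg_hits, marker_hits=marker_hits,
                      loci=loci, records=records,
                      ir_per_locus=ir_per_locus, ir_summary=ir_summary,
                      summary=summary, manifest=manifest)
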