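"""Regulator-anchored neighbourhood analysis.

Anchors on regulator homology hits, scans fixed windows either side of each
anchor for defence-marker hits, groups marker hits into system instances,
classifies the association, and summarizes by class, co-occurrence,
taxonomy, and replicon type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .genome import (Direction, GeneFeature, Genome, RepliconType,
                     distance_between, extract_upstream)
from .homology import HomologyHit

DEFAULT_WINDOW = 50_000
DEFAULT_UPSTREAM = 200
DEFAULT_CLUSTER_GAP = 20_000


def percent(numerator: int, denominator: int) -> float:
    """Exact ratio as a percentage, round-half-even to 2 dp."""
    if denominator == 0:
        return 0.0
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    return float(q)


# ---------------------------------------------------------------------------
# marker panel


@dataclass
class MarkerEntry:
    marker_id: str
    system_name: str
    system_class: str
    subtype: str = ""
    protein_seq: str = ""


@dataclass
class MarkerPanel:
    entries: dict[str, MarkerEntry] = field(default_factory=dict)

    def add(self, entry: MarkerEntry) -> None:
        if entry.marker_id in self.entries:
            raise ValueError(f"duplicate marker_id {entry.marker_id!r}")
        if not entry.system_class:
            raise ValueError(f"marker {entry.marker_id!r} lacks a system_class")
        self.entries[entry.marker_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, marker_id: str) -> MarkerEntry:
        return self.entries[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.entries

    def proteins(self) -> dict[str, str]:
        return {m.marker_id: m.protein_seq for m in self.entries.values()}

    @classmethod
    def from_files(cls, fasta_path: str | Path, tsv_path: str | Path) -> "MarkerPanel":
        """Panel from a protein FASTA plus a mapping TSV with columns
        marker_id, system_name, system_class, subtype."""
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta_path), "fasta")}
        panel = cls()
        with open(tsv_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"marker_id", "system_name", "system_class"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"panel TSV missing column(s): {sorted(missing)}")
            for row in reader:
                mid = row["marker_id"]
                panel.add(MarkerEntry(
                    marker_id=mid,
                    system_name=row["system_name"],
                    system_class=row["system_class"],
                    subtype=row.get("subtype", "") or "",
                    protein_seq=seqs.get(mid, ""),
                ))
        return panel

    def to_files(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for m in self.entries.values():
                fh.write(f">{m.marker_id}\n{m.protein_seq}\n")
        with open(tsv_path, "w") as fh:
            fh.write("marker_id\tsystem_name\tsystem_class\tsubtype\n")
            for m in self.entries.values():
                fh.write(f"{m.marker_id}\t{m.system_name}\t{m.system_class}"
                         f"\t{m.subtype}\n")


# ---------------------------------------------------------------------------
# records


@dataclass
class RegulatorLocus:
    locus_id: str
    genome_id: str
    feature: GeneFeature
    hit: HomologyHit
    replicon_type: RepliconType
    upstream_seq: str = ""


@dataclass
class SystemInstance:
    instance_id: str
    system_class: str
    system_name: str
    subtype: str
    marker_hits: list[HomologyHit]
    span: tuple[int, int]
    direction: Direction
    distance: int

    def __post_init__(self) -> None:
        if not self.marker_hits:
            raise ValueError("SystemInstance requires at least one marker hit")


@dataclass
class AssociationRecord:
    locus_id: str
    window: int
    systems_downstream: list[SystemInstance]
    systems_upstream: list[SystemInstance]

    @property
    def verdict(self) -> str:
        down, up = bool(self.systems_downstream), bool(self.systems_upstream)
        if down and up:
            return "both"
        if down:
            return "downstream_only"
        if up:
            return "upstream_only"
        return "none"


# ---------------------------------------------------------------------------
# operations


def anchor_regulators(hits: Iterable[HomologyHit], genomes: Iterable[Genome],
                      upstream_len: int = DEFAULT_UPSTREAM) -> list[RegulatorLocus]:
    """One locus per regulator hit, with upstream sequence and replicon type."""
    gmap = {g.assembly_id: g for g in genomes}
    loci = []
    for hit in hits:
        genome = gmap.get(hit.genome_id)
        feature = None
        if genome is not None:
            try:
                feature = genome.feature(hit.subject_feature_id)
            except KeyError:
                feature = None
        if feature is None and not hit.genome_id:
            # tabular ingests may omit the genome id; resolve by feature id
            for g in gmap.values():
                try:
                    feature = g.feature(hit.subject_feature_id)
                    genome = g
                    break
                except KeyError:
                    continue
        if feature is None or genome is None:
            raise ValueError(
                f"hit references unresolvable feature "
                f"{hit.genome_id!r}:{hit.subject_feature_id!r}"
            )
        rep = genome.replicons[feature.replicon_id]
        loci.append(RegulatorLocus(
            locus_id=f"{genome.assembly_id}:{feature.feature_id}",
            genome_id=genome.assembly_id,
            feature=feature,
            hit=hit,
            replicon_type=rep.replicon_type,
            upstream_seq=extract_upstream(genome, feature, upstream_len),
        ))
    return loci


def _oriented_distance(anchor: GeneFeature, other: GeneFeature,
                       direction_mode: str) -> tuple[int, Direction]:
    dist, direction = distance_between(anchor, other)
    if direction_mode == "coordinate" and direction is not Direction.OVERLAPPING:
        # higher coordinates count as downstream regardless of anchor strand
        right = other.start >= anchor.end
        direction = Direction.DOWNSTREAM if right else Direction.UPSTREAM
    return dist, direction


def scan_window(locus: RegulatorLocus,
                marker_hits: Iterable[tuple[HomologyHit, GeneFeature]],
                window: int = DEFAULT_WINDOW,
                direction: Direction = Direction.DOWNSTREAM,
                direction_mode: str = "strand") -> list[tuple[HomologyHit, GeneFeature, int]]:
    """Marker hits on the locus replicon within ``window`` bp in the
    requested direction (edge-gap distances; the anchor itself excluded).
    Markers overlapping the anchor match neither direction."""
    direction = Direction(direction)
    out = []
    for hit, feat in marker_hits:
        if feat.replicon_id != locus.feature.replicon_id:
            continue
        if feat.feature_id == locus.feature.feature_id:
            continue
        dist, d = _oriented_distance(locus.feature, feat, direction_mode)
        if d is not direction:
            continue
        if dist <= window:
            out.append((hit, feat, dist))
    out.sort(key=lambda t: (t[2], t[1].start, t[1].feature_id))
    return out


def group_systems(window_hits: Iterable[tuple[HomologyHit, GeneFeature, int]],
                  panel: MarkerPanel,
                  direction: Direction = Direction.DOWNSTREAM,
                  cluster_gap: int = DEFAULT_CLUSTER_GAP,
                  locus_id: str = "") -> list[SystemInstance]:
    """Collapse marker hits sharing a system_name into instances: hits whose
    features lie within ``cluster_gap`` of one another form one instance."""
    by_system: dict[str, list[tuple[HomologyHit, GeneFeature, int]]] = {}
    for hit, feat, dist in window_hits:
        if hit.query_id not in panel:
            raise ValueError(f"marker hit {hit.query_id!r} has no panel entry")
        by_system.setdefault(panel[hit.query_id].system_name, []).append(
            (hit, feat, dist))

    instances: list[SystemInstance] = []
    for system_name in sorted(by_system):
        members = sorted(by_system[system_name], key=lambda t: t[1].start)
        clusters: list[list[tuple[HomologyHit, GeneFeature, int]]] = []
        for item in members:
            if clusters:
                prev_feat = clusters[-1][-1][1]
                gap = max(0, item[1].start - prev_feat.end)
                if gap <= cluster_gap:
                    clusters[-1].append(item)
                    continue
            clusters.append([item])
        entry0 = panel[members[0][0].query_id]
        for ci, cluster in enumerate(clusters):
            best = min(cluster, key=lambda t: (t[0].evalue, -t[0].identity_frac))
            span = (min(f.start for _, f, _ in cluster),
                    max(f.end for _, f, _ in cluster))
            instances.append(SystemInstance(
                instance_id=f"{locus_id}|{direction.value}|{system_name}|{ci}",
                system_class=entry0.system_class,
                system_name=system_name,
                subtype=panel[best[0].query_id].subtype,
                marker_hits=[h for h, _, _ in cluster],
                span=span,
                direction=direction,
                distance=min(d for _, _, d in cluster),
            ))
    instances.sort(key=lambda i: (i.distance, i.span[0], i.instance_id))
    return instances


def classify(locus: RegulatorLocus,
             downstream_instances: list[SystemInstance],
             upstream_instances: list[SystemInstance],
             window: int = DEFAULT_WINDOW) -> AssociationRecord:
    return AssociationRecord(
        locus_id=locus.locus_id,
        window=window,
        systems_downstream=list(downstream_instances),
        systems_upstream=list(upstream_instances),
    )


def associate(loci: Iterable[RegulatorLocus],
              marker_hits: Iterable[HomologyHit],
              genomes: Iterable[Genome],
              window: int = DEFAULT_WINDOW,
              cluster_gap: int = DEFAULT_CLUSTER_GAP,
              panel: Optional[MarkerPanel] = None,
              direction_mode: str = "strand") -> list[AssociationRecord]:
    """Full anchoring-to-verdict chain for a collection of loci."""
    gmap = {g.assembly_id: g for g in genomes}
    resolved: dict[str, list[tuple[HomologyHit, GeneFeature]]] = {}
    for hit in marker_hits:
        genome = gmap[hit.genome_id]
        feat = genome.feature(hit.subject_feature_id)
        resolved.setdefault(genome.assembly_id, []).append((hit, feat))
    records = []
    for locus in loci:
        pairs = resolved.get(locus.genome_id, [])
        down = scan_window(locus, pairs, window, Direction.DOWNSTREAM, direction_mode)
        up = scan_window(locus, pairs, window, Direction.UPSTREAM, direction_mode)
        down_inst = group_systems(down, panel, Direction.DOWNSTREAM,
                                  cluster_gap, locus.locus_id)
        up_inst = group_systems(up, panel, Direction.UPSTREAM,
                                cluster_gap, locus.locus_id)
        records.append(classify(locus, down_inst, up_inst, window))
    return records


# ---------------------------------------------------------------------------
# summaries


@dataclass
class CooccurrenceTable:
    counts: dict[frozenset, int] = field(default_factory=dict)

    @property
    def associated_total(self) -> int:
        return sum(self.counts.values())

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("+".join(sorted(k)), v) for k, v in self.counts.items()]
        rows.sort(key=lambda r: (-r[1], r[0]))
        return rows


def cooccurrence(records: Iterable[AssociationRecord],
                 direction: Direction = Direction.DOWNSTREAM) -> CooccurrenceTable:
    """Count loci by the set of distinct system classes present in the
    chosen direction; unassociated loci contribute nothing."""
    direction = Direction(direction)
    table = CooccurrenceTable()
    for rec in records:
        insts = (rec.systems_downstream if direction is Direction.DOWNSTREAM
                 else rec.systems_upstream)
        classes = frozenset(i.system_class for i in insts)
        if classes:
            table.counts[classes] = table.counts.get(classes, 0) + 1
    return table


def class_distribution(records: Iterable[AssociationRecord],
                       direction: Direction = Direction.DOWNSTREAM) -> pd.DataFrame:
    """Counts and percentages of system instances by class (default:
    downstream instances, matching the conservative downstream analysis)."""
    direction = Direction(direction)
    counts: dict[str, int] = {}
    for rec in records:
        insts = (rec.systems_downstream if direction is Direction.DOWNSTREAM
                 else rec.systems_upstream)
        for inst in insts:
            counts[inst.system_class] = counts.get(inst.system_class, 0) + 1
    total = sum(counts.values())
    rows = [
        {"system_class": cls, "count": n, "percent": percent(n, total)}
        for cls, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["system_class", "count", "percent"])


def taxonomy_summary(loci: Iterable[RegulatorLocus],
                     lineage: Mapping[str, Mapping[str, str]] | pd.DataFrame,
                     ranks: tuple[str, ...] = ("phylum", "class", "genus"),
                     ) -> pd.DataFrame:
    """Per-rank locus/genome counts and locus percentages.

    ``lineage`` maps assembly_id to {rank: name}; loci whose assembly is
    absent (or lacks the rank) are binned as 'unclassified'.
    """
    if isinstance(lineage, pd.DataFrame):
        lineage = {
            row["assembly_id"]: {r: row[r] for r in ranks if r in row and pd.notna(row[r])}
            for _, row in lineage.iterrows()
        }
    loci = list(loci)
    total = len(loci)
    rows = []
    for rank in ranks:
        tally: dict[str, dict] = {}
        for locus in loci:
            name = (lineage.get(locus.genome_id) or {}).get(rank) or "unclassified"
            slot = tally.setdefault(name, {"loci": 0, "genomes": set()})
            slot["loci"] += 1
            slot["genomes"].add(locus.genome_id)
        for name, slot in sorted(tally.items(),
                                 key=lambda kv: (-kv[1]["loci"], kv[0])):
            rows.append({
                "rank": rank,
                "name": name,
                "n_loci": slot["loci"],
                "n_genomes": len(slot["genomes"]),
                "percent_loci": percent(slot["loci"], total),
            })
    return pd.DataFrame(rows, columns=["rank", "name", "n_loci", "n_genomes",
                                       "percent_loci"])


def replicon_summary(loci: Iterable[RegulatorLocus]) -> dict[str, int]:
    counts = {t.value: 0 for t in RepliconType}
    for locus in loci:
        counts[RepliconType(locus.replicon_type).value] += 1
    return counts


# ---------------------------------------------------------------------------
# TSV output


def write_loci_tsv(loci: Iterable[RegulatorLocus], path: str | Path) -> None:
    cols = ["locus_id", "genome_id", "feature_id", "replicon_id", "start",
            "end", "strand", "replicon_type", "evalue", "identity_frac",
            "upstream_len"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for l in loci:
            fh.write("\t".join(map(str, [
                l.locus_id, l.genome_id, l.feature.feature_id,
                l.feature.replicon_id, l.feature.start, l.feature.end,
                l.feature.strand, RepliconType(l.replicon_type).value,
                f"{l.hit.evalue:.6g}", f"{l.hit.identity_frac:.6g}",
                len(l.upstream_seq),
            ])) + "\n")


def write_instances_tsv(records: Iterable[AssociationRecord],
                        path: str | Path) -> None:
    cols = ["locus_id", "instance_id", "direction", "system_class",
            "system_name", "subtype", "n_markers", "distance", "span_start",
            "span_end"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            for inst in rec.systems_downstream + rec.systems_upstream:
                fh.write("\t".join(map(str, [
                    rec.locus_id, inst.instance_id, inst.direction.value,
                    inst.system_class, inst.system_name, inst.subtype,
                    len(inst.marker_hits), inst.distance,
                    inst.span[0], inst.span[1],
                ])) + "\n")


def write_associations_tsv(records: Iterable[AssociationRecord],
                           path: str | Path) -> None:
    cols = ["locus_id", "window", "verdict", "n_downstream", "n_upstream",
            "downstream_classes", "upstream_classes"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            dcls = "+".join(sorted({i.system_class
                                    for i in rec.systems_downstream}))
            ucls = "+".join(sorted({i.system_class
                                    for i in rec.systems_upstream}))
            fh.write("\t".join(map(str, [
                rec.locus_id, rec.window, rec.verdict,
                len(rec.systems_downstream), len(rec.systems_upstream),
                dcls, ucls,
            ])) + "\n")


def write_cooccurrence_tsv(table: CooccurrenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class_set\tn_loci\n")
        for key, count in table.as_rows():
            fh.write(f"{key}\t{count}\n")
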