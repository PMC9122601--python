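"""Genome domain model: replicons, gene features, standard-format I/O and
coordinate/sequence utilities.

Internal coordinates are 0-based half-open throughout; GFF3/GenBank
conversion (1-based inclusive) happens only at the file boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class ParseError(ValueError):
    """Raised when an input file violates its format grammar."""


class GenomeValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


class RepliconType(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    UNKNOWN = "unknown"


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class Direction(str, Enum):
    DOWNSTREAM = "downstream"
    UPSTREAM = "upstream"
    OVERLAPPING = "overlapping"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; involutive."""
    s = seq.upper()
    bad = set(s) - _DNA_ALPHABET
    if bad:
        raise GenomeValidationError(
            f"invalid DNA character(s): {sorted(bad)!r}"
        )
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class Replicon:
    replicon_id: str
    sequence: str
    replicon_type: RepliconType = RepliconType.UNKNOWN
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.replicon_type = RepliconType(self.replicon_type)
        self.topology = Topology(self.topology)
        if not self.sequence:
            raise GenomeValidationError(
                f"replicon {self.replicon_id!r}: empty sequence"
            )
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise GenomeValidationError(
                f"replicon {self.replicon_id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A CDS with 0-based half-open coordinates on its replicon."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: strand must be '+' or '-'"
            )
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.protein_seq is not None:
            self.protein_seq = self.protein_seq.upper()
            bad = set(self.protein_seq) - _PROTEIN_ALPHABET
            if bad:
                raise GenomeValidationError(
                    f"feature {self.feature_id!r}: invalid protein characters "
                    f"{sorted(bad)!r}"
                )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    assembly_id: str
    replicons: dict[str, Replicon] = field(default_factory=dict)
    features: list[GeneFeature] = field(default_factory=list)
    lineage: Optional[dict[str, str]] = None

    def validate(self) -> None:
        for feat in self.features:
            rep = self.replicons.get(feat.replicon_id)
            if rep is None:
                raise GenomeValidationError(
                    f"feature {feat.feature_id!r} references unknown replicon "
                    f"{feat.replicon_id!r}"
                )
            if feat.end > len(rep):
                raise GenomeValidationError(
                    f"feature {feat.feature_id!r} [{feat.start}, {feat.end}) "
                    f"exceeds replicon {feat.replicon_id!r} length {len(rep)}"
                )
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise GenomeValidationError(
                f"genome {self.assembly_id!r}: duplicate feature ids"
            )

    def features_sorted(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.replicon_id, f.start, f.end))

    def feature(self, feature_id: str) -> GeneFeature:
        for feat in self.features:
            if feat.feature_id == feature_id:
                return feat
        raise KeyError(feature_id)


# ---------------------------------------------------------------------------
# readers / writers


def _replicon_type_from_text(text: str) -> RepliconType:
    return RepliconType.PLASMID if "plasmid" in text.lower() else RepliconType.UNKNOWN


def _translate_cds(nt: str, strand: str) -> Optional[str]:
    if strand == "-":
        nt = reverse_complement(nt)
    if len(nt) % 3 != 0:
        return None
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "*")  # internal stops kept; alphabet allows '*'


def read_genome(
    fasta_path: str | Path | None = None,
    gff3_path: str | Path | None = None,
    genbank_path: str | Path | None = None,
    protein_fasta: str | Path | None = None,
    assembly_id: str | None = None,
) -> Genome:
    """Read an annotated genome from FASTA+GFF3 or from a GenBank flat file.

    CDS features become :class:`GeneFeature`; ``protein_seq`` comes from
    ``protein_fasta`` (keyed by feature id) when supplied, else from
    translating the CDS with the bacterial code (table 11). A CDS whose
    length is not a multiple of 3 and has no supplied protein is kept
    without a protein (with a warning).
    """
    if genbank_path is not None:
        genome = _read_genbank(genbank_path, assembly_id)
    elif fasta_path is not None and gff3_path is not None:
        genome = _read_fasta_gff3(fasta_path, gff3_path, assembly_id)
    else:
        raise ValueError("provide fasta_path+gff3_path or genbank_path")

    if protein_fasta is not None:
        proteins = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(protein_fasta), "fasta")
        }
        for feat in genome.features:
            if feat.feature_id in proteins:
                feat.protein_seq = proteins[feat.feature_id]

    for feat in genome.features:
        if feat.protein_seq is None:
            rep = genome.replicons[feat.replicon_id]
            nt = rep.sequence[feat.start:feat.end]
            aa = _translate_cds(nt, feat.strand)
            if aa is None:
                warnings.warn(
                    f"CDS {feat.feature_id!r} length {len(nt)} not divisible "
                    "by 3 and no protein supplied; kept without protein_seq",
                    stacklevel=2,
                )
            else:
                feat.protein_seq = aa
    genome.validate()
    return genome


def _read_fasta_gff3(fasta_path, gff3_path, assembly_id) -> Genome:
    import gffutils

    replicons: dict[str, Replicon] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        replicons[rec.id] = Replicon(
            replicon_id=rec.id,
            sequence=str(rec.seq),
            replicon_type=_replicon_type_from_text(rec.description),
        )
    if not replicons:
        raise ParseError(f"{fasta_path}: no FASTA records")

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{gff3_path}: {exc}") from exc

    features: list[GeneFeature] = []
    for f in db.all_features():
        if f.featuretype == "region":
            circ = f.attributes.get("Is_circular", ["false"])[0]
            if circ.lower() == "true" and f.seqid in replicons:
                replicons[f.seqid].topology = Topology.CIRCULAR
            rtype = f.attributes.get("genome", [""])[0]
            if rtype == "plasmid" and f.seqid in replicons:
                replicons[f.seqid].replicon_type = RepliconType.PLASMID
            elif rtype == "chromosome" and f.seqid in replicons:
                replicons[f.seqid].replicon_type = RepliconType.CHROMOSOME
            continue
        if f.featuretype != "CDS":
            continue
        fid = f.attributes.get("ID", [f.id])[0]
        product = f.attributes.get("product", [""])[0]
        if f.seqid not in replicons:
            raise GenomeValidationError(
                f"feature {fid!r} references unknown replicon {f.seqid!r}"
            )
        features.append(
            GeneFeature(
                feature_id=fid,
                replicon_id=f.seqid,
                start=f.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                product=product,
            )
        )
    aid = assembly_id or Path(str(fasta_path)).stem
    return Genome(assembly_id=aid, replicons=replicons, features=features)


def _read_genbank(genbank_path, assembly_id) -> Genome:
    replicons: dict[str, Replicon] = {}
    features: list[GeneFeature] = []
    records = list(SeqIO.parse(str(genbank_path), "genbank"))
    if not records:
        raise ParseError(f"{genbank_path}: no GenBank records")
    for rec in records:
        topo = rec.annotations.get("topology", "linear")
        replicons[rec.id] = Replicon(
            replicon_id=rec.id,
            sequence=str(rec.seq),
            replicon_type=_replicon_type_from_text(rec.description),
            topology=Topology.CIRCULAR if topo == "circular" else Topology.LINEAR,
        )
        n = 0
        for f in rec.features:
            if f.type != "CDS":
                continue
            n += 1
            fid = f.qualifiers.get(
                "locus_tag", f.qualifiers.get("protein_id", [f"{rec.id}_cds{n}"])
            )[0]
            protein = f.qualifiers.get("translation", [None])[0]
            features.append(
                GeneFeature(
                    feature_id=fid,
                    replicon_id=rec.id,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="+" if f.location.strand != -1 else "-",
                    product=f.qualifiers.get("product", [""])[0],
                    protein_seq=protein,
                )
            )
    aid = assembly_id or Path(str(genbank_path)).stem
    return Genome(assembly_id=aid, replicons=replicons, features=features)


def write_genome(genome: Genome, fasta_path: str | Path, gff3_path: str | Path) -> None:
    """Write nucleotide FASTA and GFF3 (1-based inclusive on output)."""
    with open(fasta_path, "w") as fh:
        for rep in genome.replicons.values():
            desc = ""
            if rep.replicon_type is RepliconType.PLASMID:
                desc = " plasmid"
            elif rep.replicon_type is RepliconType.CHROMOSOME:
                desc = " chromosome"
            fh.write(f">{rep.replicon_id}{desc}\n")
            for i in range(0, len(rep.sequence), 70):
                fh.write(rep.sequence[i:i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons.values():
            fh.write(f"##sequence-region {rep.replicon_id} 1 {len(rep)}\n")
        for rep in genome.replicons.values():
            attrs = [f"ID=region-{rep.replicon_id}"]
            if rep.topology is Topology.CIRCULAR:
                attrs.append("Is_circular=true")
            if rep.replicon_type is not RepliconType.UNKNOWN:
                attrs.append(f"genome={rep.replicon_type.value}")
            fh.write(
                f"{rep.replicon_id}\tislandscan\tregion\t1\t{len(rep)}\t.\t+\t.\t"
                + ";".join(attrs) + "\n"
            )
        for feat in genome.features_sorted():
            attrs = f"ID={feat.feature_id}"
            if feat.product:
                attrs += f";product={feat.product}"
            fh.write(
                f"{feat.replicon_id}\tislandscan\tCDS\t{feat.start + 1}\t{feat.end}"
                f"\t.\t{feat.strand}\t0\t{attrs}\n"
            )


def write_proteins(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for feat in genome.features_sorted():
            if feat.protein_seq:
                fh.write(f">{feat.feature_id}\n{feat.protein_seq}\n")


# ---------------------------------------------------------------------------
# coordinate / sequence utilities


def extract_upstream(
    genome: Genome,
    feature: GeneFeature,
    length: int,
    allow_wrap: bool = False,
) -> str:
    """Up to ``length`` bases 5' of ``feature`` on its coding strand.

    Truncated at the replicon edge for linear replicons; for circular
    replicons wrap-around applies only when ``allow_wrap`` is set.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    rep = genome.replicons[feature.replicon_id]
    n = len(rep)
    wrap = allow_wrap and rep.topology is Topology.CIRCULAR
    if feature.strand == "+":
        lo = feature.start - length
        if lo >= 0:
            return rep.sequence[lo:feature.start]
        if wrap:
            return rep.sequence[lo % n:] + rep.sequence[:feature.start]
        log.debug("upstream of %s truncated at replicon start", feature.feature_id)
        return rep.sequence[0:feature.start]
    hi = feature.end + length
    if hi <= n:
        return reverse_complement(rep.sequence[feature.end:hi])
    if wrap:
        return reverse_complement(rep.sequence[feature.end:] + rep.sequence[:hi - n])
    log.debug("upstream of %s truncated at replicon end", feature.feature_id)
    return reverse_complement(rep.sequence[feature.end:n])


def distance_between(anchor: GeneFeature, other: GeneFeature) -> tuple[int, Direction]:
    """Edge-gap distance and strand-aware direction of ``other`` vs ``anchor``.

    Direction is downstream when ``other`` lies 3' of the anchor on the
    anchor's coding strand; overlapping features have distance 0.
    """
    if anchor.replicon_id != other.replicon_id:
        raise ValueError(
            f"features on different replicons: {anchor.replicon_id!r} vs "
            f"{other.replicon_id!r}"
        )
    if other.start >= anchor.end:
        gap, side = other.start - anchor.end, "right"
    elif other.end <= anchor.start:
        gap, side = anchor.start - other.end, "left"
    else:
        return 0, Direction.OVERLAPPING
    if anchor.strand == "+":
        return gap, Direction.DOWNSTREAM if side == "right" else Direction.UPSTREAM
    return gap, Direction.DOWNSTREAM if side == "left" else Direction.UPSTREAM


# ---------------------------------------------------------------------------
# JSON fixture serialization


def genome_to_json(genome: Genome) -> str:
    payload = {
        "assembly_id": genome.assembly_id,
        "lineage": genome.lineage,
        "replicons": [
            {
                "replicon_id": r.replicon_id,
                "sequence": r.sequence,
                "replicon_type": r.replicon_type.value,
                "topology": r.topology.value,
            }
            for r in genome.replicons.values()
        ],
        "features": [
            {
                "feature_id": f.feature_id,
                "replicon_id": f.replicon_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "product": f.product,
                "protein_seq": f.protein_seq,
            }
            for f in genome.features
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def genome_from_json(text: str) -> Genome:
    payload = json.loads(text)
    genome = Genome(
        assembly_id=payload["assembly_id"],
        replicons={r["replicon_id"]: Replicon(**r) for r in payload["replicons"]},
        features=[GeneFeature(**f) for f in payload["features"]],
        lineage=payload.get("lineage"),
    )
    genome.validate()
    return genome
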