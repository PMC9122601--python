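"""Deterministic synthetic-data generators.

Produces annotated genomes with planted regulator homologues, defence-marker
genes at controlled distances/strands, upstream inverted repeats of
controlled geometry, and hyperbolic binding curves — each alongside a
machine-readable truth table. A single root seed fans out to per-element
child streams so editing one element does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import homology
from .emsa import BindingCurve, BindingPoint
from .genome import (Direction, GeneFeature, Genome, Replicon, RepliconType,
                     reverse_complement)
from .neighbourhood import MarkerEntry, MarkerPanel

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.array(list("ACGT"))
# bases that do NOT complement the key (used to plant arm mismatches)
_NONCOMPLEMENT = {
    "A": "ACG",  # anything but T
    "C": "ACT",  # anything but G
    "G": "AGT",  # anything but C
    "T": "CGT",  # anything but A
}


class PlacementError(ValueError):
    """Raised when a planted element cannot be placed on its replicon."""


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codon_map()


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, tags)])


def random_protein(length: int, rng: np.random.Generator,
                   composition: Optional[Sequence[str]] = None) -> str:
    pool = np.array(list(composition)) if composition else np.array(list(_AA))
    return "".join(rng.choice(pool, size=length))


def mutate_protein(protein: str, identity: float,
                   rng: np.random.Generator) -> str:
    """Substitute residues at uniformly chosen positions until the fraction
    of unchanged positions equals the target identity (rounded down)."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity target must lie in (0, 1]")
    n = len(protein)
    n_mut = int(round((1.0 - identity) * n))
    positions = rng.choice(n, size=n_mut, replace=False)
    chars = list(protein)
    for pos in positions:
        options = [a for a in _AA if a != chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice under the bacterial code."""
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
                   for aa in protein)


def make_orf(protein: str, rng: np.random.Generator) -> str:
    """ATG + back-translated protein + TAA (translation = 'M' + protein)."""
    return "ATG" + back_translate(protein, rng) + "TAA"


def alignment_identity(a: str, b: str) -> float:
    """Identical aligned columns over min(len) — the generator's similarity
    measure (robust to short spurious exact seeds)."""
    res = homology.local_align(a, b)
    matches = res.identity_frac * res.aln_len
    return matches / min(len(a), len(b)) if a and b else 0.0


# ---------------------------------------------------------------------------
# genome specs


@dataclass
class RepliconSpec:
    replicon_id: str
    length: int
    replicon_type: str = "chromosome"
    gc: float = 0.5


@dataclass
class Placement:
    replicon_id: str
    position: int
    strand: str = "+"


@dataclass
class RegulatorSpec:
    protein: str
    identity: float = 1.0
    placements: list[Placement] = field(default_factory=list)


@dataclass
class PlantedSystem:
    system_name: str
    marker_ids: list[str]
    regulator_ref: int  # index into regulator placements
    direction: str = "downstream"
    edge_gap: int = 10_000
    strand: str = "+"
    identity: float = 0.9
    intergenic: int = 100


@dataclass
class PlantedIR:
    regulator_ref: int
    arm_len: int = 20
    spacer_len: int = 5
    mismatches: int = 0
    offset: int = 20  # bp between IR 3' end and the gene 5' start
    mismatch_positions: Optional[list[int]] = None  # 0-based within arm2


@dataclass
class DecoySpec:
    count: int = 0
    length: int = 150


@dataclass
class GenomeSpec:
    assembly_id: str
    seed: int
    replicons: list[RepliconSpec]
    regulator: RegulatorSpec
    planted_systems: list[PlantedSystem] = field(default_factory=list)
    planted_irs: list[PlantedIR] = field(default_factory=list)
    decoys: DecoySpec = field(default_factory=DecoySpec)


# ---------------------------------------------------------------------------
# genome generation


class _Canvas:
    """Mutable replicon sequences with interval occupancy tracking."""

    def __init__(self, spec: GenomeSpec):
        self.seqs: dict[str, np.ndarray] = {}
        self.occupied: dict[str, list[tuple[int, int]]] = {}
        for j, rs in enumerate(spec.replicons):
            rng = _rng(spec.seed, 0, j)
            gc = rs.gc
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            self.seqs[rs.replicon_id] = rng.choice(_BASES, size=rs.length, p=probs)
            self.occupied[rs.replicon_id] = []

    def free(self, replicon_id: str, start: int, end: int) -> bool:
        if start < 0 or end > len(self.seqs[replicon_id]):
            return False
        return all(end <= s or start >= e
                   for s, e in self.occupied[replicon_id])

    def write(self, replicon_id: str, start: int, seq: str, label: str) -> None:
        end = start + len(seq)
        if not self.free(replicon_id, start, end):
            raise PlacementError(
                f"{label}: cannot place [{start}, {end}) on {replicon_id!r} "
                "(out of bounds or overlapping another planted element)")
        self.seqs[replicon_id][start:end] = list(seq)
        self.occupied[replicon_id].append((start, end))


def _plant_gene(canvas: _Canvas, replicon_id: str, start: int, strand: str,
                protein: str, feature_id: str, product: str,
                rng: np.random.Generator) -> GeneFeature:
    orf = make_orf(protein, rng)
    if strand == "-":
        canvas.write(replicon_id, start, reverse_complement(orf), feature_id)
    else:
        canvas.write(replicon_id, start, orf, feature_id)
    return GeneFeature(feature_id=feature_id, replicon_id=replicon_id,
                       start=start, end=start + len(orf), strand=strand,
                       product=product, protein_seq="M" + protein)


def generate_genome(spec: GenomeSpec, panel: Optional[MarkerPanel] = None,
                    window: int = 50_000) -> tuple[Genome, dict]:
    """Build a genome from its spec; returns the genome plus a truth table
    (planted coordinates, expected association verdicts at ``window``,
    expected grouping, IR geometry, replicon types)."""
    if spec.planted_systems and panel is None:
        raise ValueError("planted systems require a marker panel")
    canvas = _Canvas(spec)
    features: list[GeneFeature] = []
    truth: dict = {
        "assembly_id": spec.assembly_id,
        "seed": spec.seed,
        "window": window,
        "regulators": [],
        "systems": [],
        "irs": [],
        "decoys": [],
        "replicon_types": {r.replicon_id: r.replicon_type
                           for r in spec.replicons},
    }

    # regulators
    reg_feats: list[GeneFeature] = []
    for i, placement in enumerate(spec.regulator.placements):
        rng = _rng(spec.seed, 1, i)
        mutant = mutate_protein(spec.regulator.protein,
                                spec.regulator.identity, rng)
        fid = f"REG{i:02d}"
        feat = _plant_gene(canvas, placement.replicon_id, placement.position,
                           placement.strand, mutant, fid, "planted regulator",
                           rng)
        reg_feats.append(feat)
        features.append(feat)
        truth["regulators"].append({
            "feature_id": fid,
            "locus_id": f"{spec.assembly_id}:{fid}",
            "replicon_id": feat.replicon_id,
            "start": feat.start, "end": feat.end, "strand": feat.strand,
            "replicon_type": truth["replicon_types"][feat.replicon_id],
            "target_identity": spec.regulator.identity,
        })

    # planted defence systems
    planted_groups: list[dict] = []
    for si, system in enumerate(spec.planted_systems):
        rng = _rng(spec.seed, 2, si)
        anchor = reg_feats[system.regulator_ref]
        direction = Direction(system.direction)
        # side on the replicon: downstream of a + anchor is rightwards
        rightwards = (direction is Direction.DOWNSTREAM) == (anchor.strand == "+")
        marker_fids = []
        marker_feats: list[GeneFeature] = []
        cursor = None
        for mi, marker_id in enumerate(system.marker_ids):
            entry = panel[marker_id]
            mutant = mutate_protein(entry.protein_seq, system.identity, rng)
            orf_len = 3 * (len(mutant) + 2)
            if rightwards:
                start = (anchor.end + system.edge_gap if cursor is None
                         else cursor + system.intergenic)
                cursor = start + orf_len
            else:
                end = (anchor.start - system.edge_gap if cursor is None
                       else cursor - system.intergenic)
                start = end - orf_len
                cursor = start
            fid = f"SYS{si:02d}_M{mi}"
            feat = _plant_gene(canvas, anchor.replicon_id, start,
                               system.strand, mutant, fid,
                               f"planted {system.system_name} marker", rng)
            features.append(feat)
            marker_fids.append(fid)
            marker_feats.append(feat)
        planted_groups.append({
            "system_name": system.system_name,
            "system_class": panel[system.marker_ids[0]].system_class,
            "features": marker_feats,
        })
        truth["systems"].append({
            "system_name": system.system_name,
            "system_class": panel[system.marker_ids[0]].system_class,
            "marker_ids": list(system.marker_ids),
            "marker_feature_ids": marker_fids,
            "regulator_feature_id": anchor.feature_id,
            "direction": direction.value,
            "edge_gap": system.edge_gap,
            "within_window": system.edge_gap <= window,
            "expected_instances": 1,
        })

    # planted upstream inverted repeats
    for ii, ir in enumerate(spec.planted_irs):
        rng = _rng(spec.seed, 3, ii)
        anchor = reg_feats[ir.regulator_ref]
        arm1 = "".join(rng.choice(_BASES, size=ir.arm_len))
        spacer = "".join(rng.choice(_BASES, size=ir.spacer_len))
        arm2 = list(reverse_complement(arm1))
        if ir.mismatch_positions is not None:
            positions = list(ir.mismatch_positions)
        else:
            positions = list(rng.choice(ir.arm_len, size=ir.mismatches,
                                        replace=False))
        if len(positions) != ir.mismatches:
            raise ValueError("mismatch_positions inconsistent with mismatches")
        for pos in positions:
            opts = _NONCOMPLEMENT[arm1[ir.arm_len - 1 - pos]]
            arm2[pos] = opts[int(rng.integers(len(opts)))]
        ir_seq = arm1 + spacer + "".join(arm2)
        total = len(ir_seq)
        if anchor.strand == "+":
            start = anchor.start - ir.offset - total
            canvas.write(anchor.replicon_id, start, ir_seq, f"IR{ii}")
        else:
            start = anchor.end + ir.offset
            canvas.write(anchor.replicon_id, start,
                         reverse_complement(ir_seq), f"IR{ii}")
        truth["irs"].append({
            "regulator_feature_id": anchor.feature_id,
            "locus_id": f"{spec.assembly_id}:{anchor.feature_id}",
            "arm_len": ir.arm_len,
            "spacer_len": ir.spacer_len,
            "mismatches": ir.mismatches,
            "offset": ir.offset,
            "arm1_seq": arm1,
            "arm2_seq": "".join(arm2),
        })

    # decoys: shuffled-composition proteins, uniform placement
    composition = None
    if panel is not None and len(panel):
        composition = "".join(m.protein_seq for m in panel.entries.values())
    for di in range(spec.decoys.count):
        rng = _rng(spec.seed, 4, di)
        protein = random_protein(spec.decoys.length, rng, composition)
        orf_len = 3 * (len(protein) + 2)
        rs = spec.replicons[int(rng.integers(len(spec.replicons)))]
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, max(1, rs.length - orf_len)))
            if canvas.free(rs.replicon_id, start, start + orf_len):
                strand = "+" if rng.integers(2) else "-"
                fid = f"DEC{di:02d}"
                feat = _plant_gene(canvas, rs.replicon_id, start, strand,
                                   protein, fid, "decoy", rng)
                features.append(feat)
                truth["decoys"].append({"feature_id": fid,
                                        "replicon_id": rs.replicon_id,
                                        "start": start})
                placed = True
                break
        if not placed:
            raise PlacementError(f"decoy {di}: no free placement found")

    # expected associations at the stated window, computed geometrically
    # from the planted coordinates over ALL regulator/system pairs (a
    # system planted for one regulator can fall inside another's window)
    def _gap_dir(anchor: GeneFeature, other: GeneFeature):
        if other.start >= anchor.end:
            gap, right = other.start - anchor.end, True
        elif other.end <= anchor.start:
            gap, right = anchor.start - other.end, False
        else:
            return 0, "overlapping"
        if anchor.strand == "+":
            return gap, "downstream" if right else "upstream"
        return gap, "downstream" if not right else "upstream"

    associations: dict[str, dict[str, list]] = {}
    verdicts = {}
    for reg_feat in reg_feats:
        locus_id = f"{spec.assembly_id}:{reg_feat.feature_id}"
        sides: dict[str, list] = {"downstream": [], "upstream": []}
        for group in planted_groups:
            members: dict[str, list[str]] = {"downstream": [], "upstream": []}
            for feat in group["features"]:
                if feat.replicon_id != reg_feat.replicon_id:
                    continue
                gap, direction = _gap_dir(reg_feat, feat)
                if direction in members and gap <= window:
                    members[direction].append(feat.feature_id)
            for direction, fids in members.items():
                if fids:
                    sides[direction].append({
                        "system_name": group["system_name"],
                        "system_class": group["system_class"],
                        "marker_feature_ids": sorted(fids),
                    })
        for direction in sides:
            sides[direction].sort(key=lambda s: s["system_name"])
        associations[locus_id] = sides
        down, up = bool(sides["downstream"]), bool(sides["upstream"])
        verdicts[locus_id] = ("both" if down and up else
                              "downstream_only" if down else
                              "upstream_only" if up else "none")
    truth["associations"] = associations
    truth["expected_verdicts"] = verdicts

    replicons = {
        rs.replicon_id: Replicon(
            replicon_id=rs.replicon_id,
            sequence="".join(canvas.seqs[rs.replicon_id]),
            replicon_type=RepliconType(rs.replicon_type),
        )
        for rs in spec.replicons
    }
    genome = Genome(assembly_id=spec.assembly_id, replicons=replicons,
                    features=features)
    genome.validate()
    return genome, truth


# ---------------------------------------------------------------------------
# marker panel generation

_CLASS_ROSTER = [
    "BREX", "Type I RM", "Type IV restriction", "CRISPR-Cas", "CBASS",
    "Wadjet", "Zorya", "Thoeris", "Pycsar", "TA type II",
]


def generate_panel(n_systems: int, markers_per_system: int, seed: int = 0,
                   length: int = 120, max_identity: float = 0.5,
                   check: bool = True) -> MarkerPanel:
    """Random, mutually dissimilar marker proteins grouped into systems.

    Pairwise alignment identity between distinct markers is verified to sit
    below ``max_identity`` (matches over min length) when ``check`` is on.
    """
    panel = MarkerPanel()
    proteins: list[tuple[str, str]] = []
    for i in range(n_systems):
        cls = _CLASS_ROSTER[i % len(_CLASS_ROSTER)]
        name = f"{cls} system {i}"
        for j in range(markers_per_system):
            rng = _rng(seed, 10, i, j)
            marker_id = f"MRK{i:02d}_{j}"
            for attempt in range(50):
                candidate = random_protein(length, rng)
                if not check or all(
                        alignment_identity(candidate, p) < max_identity
                        for _, p in proteins):
                    break
            else:
                raise RuntimeError(
                    f"could not generate dissimilar marker {marker_id}")
            proteins.append((marker_id, candidate))
            panel.add(MarkerEntry(
                marker_id=marker_id,
                system_name=name,
                system_class=cls,
                subtype=f"subtype {j}",
                protein_seq=candidate,
            ))
    return panel


def generate_regulator_protein(length: int = 280, seed: int = 0) -> str:
    return random_protein(length, _rng(seed, 11))


# ---------------------------------------------------------------------------
# binding data


def generate_binding_data(kd: float, ymax: float, concs: Sequence[float],
                          sigma: float, replicates: int, seed: int,
                          probe_id: str = "probe") -> BindingCurve:
    """Hyperbolic isotherm plus Gaussian noise, expressed as intensities
    with I_C = 1 (I_T clipped at 0 where noise pushes Y above 1)."""
    rng = _rng(seed, 20)
    curve = BindingCurve(probe_id=probe_id)
    for conc in concs:
        y0 = ymax * conc / (kd + conc)
        for rep in range(1, replicates + 1):
            y = y0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            curve.points.append(BindingPoint(
                conc=float(conc),
                i_test=max(0.0, 1.0 - y),
                i_control=1.0,
                replicate=rep,
            ))
    return curve


# ---------------------------------------------------------------------------
# lineage


def generate_lineage(assembly_ids: Sequence[str],
                     allocations: Sequence[tuple[int, dict[str, str]]],
                     fill: Optional[dict[str, str]] = None) -> "pd.DataFrame":
    """Assign lineages to assemblies in order: each (count, {rank: name})
    allocation consumes the next ``count`` ids. Remaining ids get ``fill``
    (or no row at all when fill is None, leaving them unclassified)."""
    import pandas as pd

    rows = []
    idx = 0
    for count, ranks in allocations:
        for _ in range(count):
            if idx >= len(assembly_ids):
                raise ValueError("allocations exceed the number of assemblies")
            rows.append({"assembly_id": assembly_ids[idx], **ranks})
            idx += 1
    if fill is not None:
        for aid in assembly_ids[idx:]:
            rows.append({"assembly_id": aid, **fill})
    return pd.DataFrame(rows)


def lineage_to_mapping(df) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["assembly_id"]] = {
            k: v for k, v in row.items()
            if k != "assembly_id" and isinstance(v, str)
        }
    return out


# ---------------------------------------------------------------------------
# corpus convenience


def default_corpus_specs(n_genomes: int, panel: MarkerPanel,
                         regulator_protein: str, seed: int = 0,
                         window: int = 50_000) -> list[GenomeSpec]:
    """A varied desk-scale corpus: gaps straddling the window, both
    directions and strands, plasmids, decoys, and planted upstream IRs."""
    gap_cycle = [10_000, 49_999, 50_000, 50_001, 60_000, 25_000, 5_000, 40_000]
    marker_ids = sorted(panel.entries)
    systems_by_name: dict[str, list[str]] = {}
    for mid in marker_ids:
        systems_by_name.setdefault(panel[mid].system_name, []).append(mid)
    system_names = sorted(systems_by_name)

    specs = []
    for g in range(n_genomes):
        strand = "+" if g % 2 == 0 else "-"
        on_plasmid = g % 5 == 4
        replicons = [RepliconSpec("chr", 160_000, "chromosome")]
        if on_plasmid:
            replicons.append(RepliconSpec("pls", 160_000, "plasmid"))
        home = "pls" if on_plasmid else "chr"
        placements = [Placement(home, 75_000, strand)]
        two_loci = g % 7 == 3
        if two_loci:
            placements.append(Placement("chr" if on_plasmid else home,
                                        15_000 if on_plasmid else 152_000,
                                        "+"))
        planted = []
        gap = gap_cycle[g % len(gap_cycle)]
        name = system_names[g % len(system_names)]
        planted.append(PlantedSystem(
            system_name=name,
            marker_ids=systems_by_name[name],
            regulator_ref=0,
            direction="downstream",
            edge_gap=gap,
            strand="+" if g % 3 else "-",
        ))
        if g % 4 == 1:
            name2 = system_names[(g + 3) % len(system_names)]
            planted.append(PlantedSystem(
                system_name=name2,
                marker_ids=systems_by_name[name2][:1],
                regulator_ref=0,
                direction="upstream",
                edge_gap=gap_cycle[(g + 2) % len(gap_cycle)],
                strand="+",
            ))
        irs = []
        if g % 2 == 0:
            irs.append(PlantedIR(regulator_ref=0, arm_len=20, spacer_len=5,
                                 mismatches=g % 3, offset=30))
        specs.append(GenomeSpec(
            assembly_id=f"GSYN{g:03d}",
            seed=seed * 10_000 + g,
            replicons=replicons,
            regulator=RegulatorSpec(protein=regulator_protein, identity=0.7,
                                    placements=placements),
            planted_systems=planted,
            planted_irs=irs,
            decoys=DecoySpec(count=3, length=140),
        ))
    return specs


def write_truth(truths: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(list(truths), fh, indent=1, sort_keys=True)
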