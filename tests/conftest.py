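import numpy as np
import pytest

from islandscan import synth
from islandscan.genome import Direction, GeneFeature, Genome, Replicon
from islandscan.homology import HomologyHit
from islandscan.neighbourhood import (AssociationRecord, MarkerEntry,
                                      MarkerPanel, RegulatorLocus,
                                      SystemInstance)


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return synth.generate_panel(n_systems=5, markers_per_system=2, seed=7)


@pytest.fixture(scope="session")
def regulator_protein() -> str:
    return synth.generate_regulator_protein(length=280, seed=7)


@pytest.fixture(scope="session")
def small_corpus(panel, regulator_protein):
    """Six synthetic genomes with their truth tables."""
    specs = synth.default_corpus_specs(6, panel, regulator_protein, seed=7)
    out = []
    for spec in specs:
        out.append(synth.generate_genome(spec, panel))
    return out


def make_feature(feature_id="F1", replicon_id="chr", start=1000, end=2000,
                 strand="+", protein_seq=None) -> GeneFeature:
    return GeneFeature(feature_id=feature_id, replicon_id=replicon_id,
                       start=start, end=end, strand=strand,
                       protein_seq=protein_seq)


def make_genome(length=20_000, assembly_id="G1", features=(),
                replicon_type="chromosome", seed=0) -> Genome:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    genome = Genome(
        assembly_id=assembly_id,
        replicons={"chr": Replicon("chr", seq, replicon_type)},
        features=list(features),
    )
    genome.validate()
    return genome


def make_hit(query_id="Q", feature_id="F1", genome_id="G1", evalue=1e-10,
             identity=0.9) -> HomologyHit:
    return HomologyHit(query_id=query_id, subject_feature_id=feature_id,
                       genome_id=genome_id, score=100.0, bitscore=40.0,
                       evalue=evalue, identity_frac=identity)


def make_locus(locus_id="L1", genome_id="G1", feature=None,
               replicon_type="chromosome", upstream_seq="") -> RegulatorLocus:
    feature = feature or make_feature()
    return RegulatorLocus(locus_id=locus_id, genome_id=genome_id,
                          feature=feature, hit=make_hit(),
                          replicon_type=replicon_type,
                          upstream_seq=upstream_seq)


def make_instance(system_class="BREX", system_name=None, n_markers=1,
                  direction=Direction.DOWNSTREAM, distance=1000,
                  instance_id="I") -> SystemInstance:
    return SystemInstance(
        instance_id=instance_id,
        system_class=system_class,
        system_name=system_name or f"{system_class} system",
        subtype="",
        marker_hits=[make_hit(query_id=f"M{k}") for k in range(n_markers)],
        span=(5000, 6000),
        direction=Direction(direction),
        distance=distance,
    )


def make_record(locus_id="L1", down_classes=(), up_classes=(),
                window=50_000) -> AssociationRecord:
    return AssociationRecord(
        locus_id=locus_id,
        window=window,
        systems_downstream=[make_instance(c, instance_id=f"{locus_id}-d{k}")
                            for k, c in enumerate(down_classes)],
        systems_upstream=[make_instance(c, direction=Direction.UPSTREAM,
                                        instance_id=f"{locus_id}-u{k}")
                         for k, c in enumerate(up_classes)],
    )
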