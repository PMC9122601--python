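import itertools

import pytest

from islandscan.genome import Direction
from islandscan.neighbourhood import (AssociationRecord, MarkerEntry,
                                      MarkerPanel, anchor_regulators,
                                      associate, class_distribution, classify,
                                      cooccurrence, group_systems, percent,
                                      replicon_summary, scan_window,
                                      taxonomy_summary)

from conftest import (make_feature, make_genome, make_hit, make_instance,
                      make_locus, make_record)


def _panel_of(*entries) -> MarkerPanel:
    panel = MarkerPanel()
    for marker_id, system_name, system_class in entries:
        panel.add(MarkerEntry(marker_id, system_name, system_class,
                              protein_seq="M" * 20))
    return panel


class TestPercent:
    @pytest.mark.parametrize("num,den,expected", [
        (212, 347, 61.10), (338, 347, 97.41), (70, 210, 33.33),
        (21, 210, 10.00), (34, 210, 16.19), (24, 347, 6.92),
    ])
    def test_published_ratios(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_even(self):
        assert percent(125, 10000) == 1.25
        assert percent(1, 1) == 100.0


class TestMarkerPanel:
    def test_duplicate_marker_rejected(self):
        panel = _panel_of(("m1", "BREX sys", "BREX"))
        with pytest.raises(ValueError):
            panel.add(MarkerEntry("m1", "x", "y"))

    def test_missing_class_rejected(self):
        panel = MarkerPanel()
        with pytest.raises(ValueError):
            panel.add(MarkerEntry("m1", "x", ""))

    def test_file_round_trip(self, tmp_path, panel):
        panel.to_files(tmp_path / "p.faa", tmp_path / "p.tsv")
        back = MarkerPanel.from_files(tmp_path / "p.faa", tmp_path / "p.tsv")
        assert set(back.entries) == set(panel.entries)
        for mid in panel.entries:
            assert back[mid].system_class == panel[mid].system_class
            assert back[mid].protein_seq == panel[mid].protein_seq


class TestAnchorRegulators:
    def test_two_loci_one_genome(self):
        feats = [make_feature("r1", start=1000, end=2000),
                 make_feature("r2", start=9000, end=9900)]
        genome = make_genome(features=feats)
        hits = [make_hit(feature_id="r1"), make_hit(feature_id="r2")]
        loci = anchor_regulators(hits, [genome])
        assert len(loci) == 2
        assert len({l.genome_id for l in loci}) == 1

    def test_upstream_truncated_at_edge(self):
        genome = make_genome(features=[make_feature("r1", start=120, end=900)])
        loci = anchor_regulators([make_hit(feature_id="r1")], [genome])
        assert len(loci[0].upstream_seq) == 120

    def test_no_hits(self):
        assert anchor_regulators([], [make_genome()]) == []

    def test_dangling_reference(self):
        with pytest.raises(ValueError, match="unresolvable"):
            anchor_regulators([make_hit(feature_id="ghost")], [make_genome()])


class TestScanWindow:
    def _setup(self, marker_start, marker_end, anchor_strand="+"):
        anchor = make_feature("reg", start=100_000, end=101_000,
                              strand=anchor_strand)
        marker = make_feature("mk", start=marker_start, end=marker_end)
        locus = make_locus(feature=anchor)
        return locus, [(make_hit(query_id="M", feature_id="mk"), marker)]

    def test_within_window_included_with_distance(self):
        locus, pairs = self._setup(111_000, 112_000)
        out = scan_window(locus, pairs, window=50_000,
                          direction=Direction.DOWNSTREAM)
        assert len(out) == 1 and out[0][2] == 10_000

    def test_boundary_at_window_included(self):
        locus, pairs = self._setup(151_000, 152_000)
        assert scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)

    def test_one_past_window_excluded(self):
        locus, pairs = self._setup(151_001, 152_000)
        assert not scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)

    def test_direction_filtering(self):
        locus, pairs = self._setup(85_000, 90_000)  # 10 kb upstream of +
        assert not scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)
        up = scan_window(locus, pairs, 50_000, Direction.UPSTREAM)
        assert len(up) == 1 and up[0][2] == 10_000

    def test_anchor_excluded_from_own_window(self):
        anchor = make_feature("reg", start=100_000, end=101_000)
        locus = make_locus(feature=anchor)
        pairs = [(make_hit(query_id="M", feature_id="reg"), anchor)]
        assert not scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)

    def test_other_replicon_excluded(self):
        anchor = make_feature("reg", start=100_000, end=101_000)
        locus = make_locus(feature=anchor)
        other = make_feature("mk", replicon_id="pls", start=101_500,
                             end=102_000)
        pairs = [(make_hit(query_id="M", feature_id="mk"), other)]
        assert not scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)

    def test_coordinate_mode(self):
        # anchor on -: 10 kb to the right is upstream in strand mode,
        # downstream in coordinate mode
        locus, pairs = self._setup(111_000, 112_000, anchor_strand="-")
        assert not scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM)
        got = scan_window(locus, pairs, 50_000, Direction.DOWNSTREAM,
                          direction_mode="coordinate")
        assert len(got) == 1


class TestGroupSystems:
    def _window_hits(self, items):
        # items: (marker_id, start, end)
        return [(make_hit(query_id=mid, feature_id=f"f{k}", evalue=1e-10),
                 make_feature(f"f{k}", start=s, end=e), s - 101_000)
                for k, (mid, s, e) in enumerate(items)]

    def test_three_markers_one_instance(self):
        panel = _panel_of(("b1", "BREX sys", "BREX"), ("b2", "BREX sys", "BREX"),
                          ("b3", "BREX sys", "BREX"))
        hits = self._window_hits([("b1", 110_000, 111_000),
                                  ("b2", 114_000, 115_000),
                                  ("b3", 117_000, 118_000)])
        instances = group_systems(hits, panel)
        assert len(instances) == 1
        assert len(instances[0].marker_hits) == 3
        assert instances[0].span == (110_000, 118_000)

    def test_different_classes_two_instances(self):
        panel = _panel_of(("b1", "BREX sys", "BREX"),
                          ("t1", "TypeIV sys", "Type IV restriction"))
        hits = self._window_hits([("b1", 110_000, 111_000),
                                  ("t1", 116_000, 117_000)])
        instances = group_systems(hits, panel)
        assert len(instances) == 2
        assert {i.system_class for i in instances} == {
            "BREX", "Type IV restriction"}

    def test_same_system_beyond_cluster_gap_splits(self):
        panel = _panel_of(("b1", "BREX sys", "BREX"))
        hits = self._window_hits([("b1", 110_000, 111_000),
                                  ("b1", 141_000, 142_000)])  # 30 kb apart
        instances = group_systems(hits, panel, cluster_gap=20_000)
        assert len(instances) == 2

    def test_missing_panel_mapping_rejected(self):
        panel = _panel_of(("b1", "BREX sys", "BREX"))
        hits = self._window_hits([("zz", 110_000, 111_000)])
        with pytest.raises(ValueError, match="panel"):
            group_systems(hits, panel)

    def test_subtype_from_best_evalue_hit(self):
        panel = MarkerPanel()
        panel.add(MarkerEntry("b1", "BREX sys", "BREX", subtype="type 1"))
        panel.add(MarkerEntry("b2", "BREX sys", "BREX", subtype="type 2"))
        hits = [
            (make_hit(query_id="b1", feature_id="f0", evalue=1e-8),
             make_feature("f0", start=110_000, end=111_000), 9_000),
            (make_hit(query_id="b2", feature_id="f1", evalue=1e-20),
             make_feature("f1", start=112_000, end=113_000), 11_000),
        ]
        instances = group_systems(hits, panel)
        assert instances[0].subtype == "type 2"


class TestClassify:
    def test_verdicts(self):
        locus = make_locus()
        down = [make_instance("BREX")]
        up = [make_instance("CBASS", direction=Direction.UPSTREAM)]
        assert classify(locus, down, []).verdict == "downstream_only"
        assert classify(locus, [], up).verdict == "upstream_only"
        assert classify(locus, down, up).verdict == "both"
        assert classify(locus, [], []).verdict == "none"


class TestCooccurrence:
    def test_example_sets(self):
        records = [
            make_record("l1", down_classes=("BREX",)),
            make_record("l2", down_classes=("BREX", "Type IV restriction")),
            make_record("l3"),
        ]
        table = cooccurrence(records)
        assert table.counts == {
            frozenset({"BREX"}): 1,
            frozenset({"BREX", "Type IV restriction"}): 1,
        }
        assert table.associated_total == 2

    def test_all_unassociated_empty(self):
        assert cooccurrence([make_record(), make_record()]).counts == {}

    def test_singleton_counts_match_brute_force(self):
        # brute-force UpSet decomposition over a fixture of class sets
        sets = [{"BREX"}, {"BREX"}, {"CBASS"}, {"BREX", "CBASS"},
                {"Zorya", "CBASS"}, set(), {"Zorya"}]
        records = [make_record(f"l{k}", down_classes=tuple(sorted(s)))
                   for k, s in enumerate(sets)]
        table = cooccurrence(records)
        for cls in {"BREX", "CBASS", "Zorya"}:
            alone = sum(1 for s in sets if s == {cls})
            assert table.counts.get(frozenset({cls}), 0) == alone
        assert table.associated_total == sum(1 for s in sets if s)


class TestClassDistribution:
    def test_seventy_of_210(self):
        records = ([make_record(f"a{k}", down_classes=("BREX",))
                    for k in range(70)]
                   + [make_record(f"b{k}", down_classes=("Other",))
                      for k in range(140)])
        table = class_distribution(records)
        brex = table[table.system_class == "BREX"].iloc[0]
        assert brex["count"] == 70
        assert brex["percent"] == 33.33
        assert table["count"].sum() == 210

    def test_single_instance_is_100(self):
        table = class_distribution([make_record("l", down_classes=("BREX",))])
        assert table.iloc[0]["percent"] == 100.00

    def test_percents_sum_to_100(self):
        records = [make_record(f"l{k}", down_classes=(f"C{k % 7}",))
                   for k in range(347)]
        table = class_distribution(records)
        assert abs(table["percent"].sum() - 100.0) <= 0.05


class TestTaxonomySummary:
    def _loci(self, n):
        return [make_locus(locus_id=f"l{k}", genome_id=f"g{k}")
                for k in range(n)]

    def test_24_of_347_genus(self):
        loci = self._loci(347)
        lineage = {f"g{k}": {"genus": "Pseudomonas"} for k in range(24)}
        table = taxonomy_summary(loci, lineage, ranks=("genus",))
        row = table[table.name == "Pseudomonas"].iloc[0]
        assert row["n_loci"] == 24
        assert row["percent_loci"] == 6.92

    def test_338_of_347_phylum(self):
        loci = self._loci(347)
        lineage = {f"g{k}": {"phylum": "Proteobacteria"} for k in range(338)}
        table = taxonomy_summary(loci, lineage, ranks=("phylum",))
        row = table[table.name == "Proteobacteria"].iloc[0]
        assert row["percent_loci"] == 97.41

    def test_empty_lineage_all_unclassified(self):
        loci = self._loci(10)
        table = taxonomy_summary(loci, {}, ranks=("phylum",))
        assert list(table.name) == ["unclassified"]
        assert table.iloc[0]["percent_loci"] == 100.0


class TestRepliconSummary:
    def test_all_plasmid(self):
        loci = [make_locus(locus_id=f"l{k}", replicon_type="plasmid")
                for k in range(4)]
        assert replicon_summary(loci) == {"chromosome": 0, "plasmid": 4,
                                          "unknown": 0}

    def test_empty(self):
        assert replicon_summary([]) == {"chromosome": 0, "plasmid": 0,
                                        "unknown": 0}


class TestAssociateProperties:
    def _run(self, small_corpus, panel, regulator_protein, window=50_000,
             evalue_max=1e-5):
        from islandscan.homology import SearchThresholds, search
        genomes = [g for g, _ in small_corpus]
        thr = SearchThresholds(evalue_max=evalue_max)
        reg_hits = search({"Q": regulator_protein}, genomes, thresholds=thr)
        marker_hits = search(panel.proteins(), genomes, thresholds=thr)
        loci = anchor_regulators(reg_hits, genomes)
        records = associate(loci, marker_hits, genomes, window=window,
                            panel=panel)
        return loci, records

    def test_verdict_partition(self, small_corpus, panel, regulator_protein):
        loci, records = self._run(small_corpus, panel, regulator_protein)
        tally = {"downstream_only": 0, "upstream_only": 0, "both": 0, "none": 0}
        for rec in records:
            tally[rec.verdict] += 1
        assert sum(tally.values()) == len(loci)

    def test_window_monotonicity(self, small_corpus, panel, regulator_protein):
        _, small = self._run(small_corpus, panel, regulator_protein,
                             window=20_000)
        _, large = self._run(small_corpus, panel, regulator_protein,
                             window=60_000)
        assoc_small = {r.locus_id for r in small if r.verdict != "none"}
        assoc_large = {r.locus_id for r in large if r.verdict != "none"}
        assert assoc_small <= assoc_large

    def test_evalue_threshold_monotonicity(self, small_corpus, panel,
                                           regulator_protein):
        loci_strict, strict = self._run(small_corpus, panel,
                                        regulator_protein, evalue_max=1e-5)
        loci_loose, loose = self._run(small_corpus, panel, regulator_protein,
                                      evalue_max=1e-3)
        assert ({l.locus_id for l in loci_strict}
                <= {l.locus_id for l in loci_loose})
        n_inst = lambda recs: sum(len(r.systems_downstream)
                                  + len(r.systems_upstream) for r in recs)
        assert n_inst(strict) <= n_inst(loose)

    def test_cooccurrence_total_matches_downstream_loci(
            self, small_corpus, panel, regulator_protein):
        _, records = self._run(small_corpus, panel, regulator_protein)
        table = cooccurrence(records)
        n_down = sum(1 for r in records if r.systems_downstream)
        assert table.associated_total == n_down
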