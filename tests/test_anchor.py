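"""Marker placement, the two-marker rule, linkage-group assignment,
scaffold ordering/orientation, AGP construction and coordinate liftover."""

import numpy as np
import pytest

from ampminer import anchor, synthetic
from ampminer._util import revcomp


def mk(marker_id, lg, cm, flank="ACGT" * 10):
    return anchor.Marker(marker_id, lg, cm, flank)


class TestPlacement:
    def test_unique_flank_placed_at_offset(self):
        scaffold = "T" * 120 + "ACCGTTGCAACCGGTTAAGGCCTTAACC" + "T" * 60
        flank = scaffold[120:148]
        placements, dropped = anchor.place_markers(
            [mk("m1", 1, 0.0, flank)], {"S": scaffold}
        )
        assert dropped == []
        (p,) = placements
        assert (p.scaffold_id, p.offset, p.strand) == ("S", 120, "+")

    def test_reverse_complement_flank_placed_minus(self):
        scaffold = "T" * 50 + "ACCGTTGCAACCGGTTAAGGCCTTAACC" + "T" * 50
        flank = revcomp(scaffold[50:78])
        placements, _ = anchor.place_markers([mk("m1", 1, 0.0, flank)],
                                             {"S": scaffold})
        assert placements[0].strand == "-"
        assert placements[0].offset == 50

    def test_duplicate_flank_dropped_as_ambiguous(self):
        motif = "ACCGTTGCAACCGGTTAAGGCCTTAACC"
        placements, dropped = anchor.place_markers(
            [mk("m1", 1, 0.0, motif)],
            {"S1": "T" * 30 + motif, "S2": motif + "G" * 30},
        )
        assert placements == []
        assert dropped == [("m1", "ambiguous")]

    def test_absent_flank_dropped(self):
        placements, dropped = anchor.place_markers(
            [mk("m1", 1, 0.0, "A" * 25)], {"S": "C" * 100}
        )
        assert dropped == [("m1", "absent")]

    def test_synthetic_markers_all_placed_at_truth(self, study):
        truth = study["truth"]
        placements, dropped = anchor.place_markers(
            study["markers"], truth.scaffolds
        )
        assert dropped == []
        by_id = {p.marker_id: p for p in placements}
        for m in truth.marker_truth:
            p = by_id[m.marker_id]
            assert (p.scaffold_id, p.offset, p.strand) == (m.scaffold_id, m.offset, "+")


class TestMinMarkerRule:
    def test_scaffolds_below_two_markers_excluded(self):
        placements = [
            anchor.MarkerPlacement("m1", "S1", 0, "+"),
            anchor.MarkerPlacement("m2", "S2", 0, "+"),
            anchor.MarkerPlacement("m3", "S2", 50, "+"),
        ]
        eligible, excluded = anchor.enforce_min_markers(placements, 2)
        assert set(eligible) == {"S2"}
        assert excluded == ["S1"]

    def test_matches_count_filter_oracle(self):
        rng = np.random.default_rng(12)
        placements = [
            anchor.MarkerPlacement(f"m{i}", f"S{rng.integers(8)}", i, "+")
            for i in range(60)
        ]
        eligible, excluded = anchor.enforce_min_markers(placements, 3)
        from collections import Counter
        counts = Counter(p.scaffold_id for p in placements)
        assert set(eligible) == {s for s, c in counts.items() if c >= 3}
        assert set(excluded) == {s for s, c in counts.items() if c < 3}


class TestAssignment:
    def _markers(self, lgs, cms=None):
        cms = cms or [10.0 + i for i in range(len(lgs))]
        markers = {f"m{i}": mk(f"m{i}", lg, cm) for i, (lg, cm) in
                   enumerate(zip(lgs, cms))}
        placements = [
            anchor.MarkerPlacement(f"m{i}", "S", 100 * i, "+")
            for i in range(len(lgs))
        ]
        return placements, markers

    def test_unanimous_vote(self):
        placements, markers = self._markers([3, 3, 3])
        a = anchor.assign_linkage_group("S", placements, markers)
        assert (a.linkage_group, a.n_markers) == (3, 3)
        assert a.anchor_cM == 11.0  # median of 10, 11, 12

    def test_majority_vote_ignores_minority(self):
        placements, markers = self._markers([3, 3, 7])
        a = anchor.assign_linkage_group("S", placements, markers)
        assert a.linkage_group == 3
        assert a.anchor_cM == 10.5  # median of the two LG-3 markers only

    def test_tie_is_conflicted(self):
        placements, markers = self._markers([3, 7])
        assert anchor.assign_linkage_group("S", placements, markers) is None


class TestOrientation:
    def _assign(self, offsets, cms):
        markers = {f"m{i}": mk(f"m{i}", 1, cm) for i, cm in enumerate(cms)}
        placements = [
            anchor.MarkerPlacement(f"m{i}", "S", off, "+")
            for i, off in enumerate(offsets)
        ]
        return anchor.assign_linkage_group("S", placements, markers)

    def test_increasing_cm_is_forward(self):
        assert self._assign([1000, 50_000], [10.0, 12.5]).orientation == "+"

    def test_decreasing_cm_is_reverse(self):
        assert self._assign([1000, 50_000], [12.5, 10.0]).orientation == "-"

    def test_flat_cm_is_unknown(self):
        assert self._assign([1000, 50_000], [10.0, 10.0]).orientation == "?"


class TestBuild:
    def _two_scaffold_build(self, orientation2="+", gap=100):
        scaffolds = {"A": "ACGT" * 250, "B": "GGCC" * 250}
        orders = {1: [("A", "+"), ("B", orientation2)]}
        return scaffolds, anchor.build_pseudochromosomes(orders, scaffolds,
                                                         gap_length=gap)

    def test_length_arithmetic_with_gap(self):
        _, builds = self._two_scaffold_build()
        assert builds["Chr1"].length == 1000 + 100 + 1000

    def test_minus_scaffold_appears_reverse_complemented(self):
        scaffolds, builds = self._two_scaffold_build("-")
        seq = anchor.build_sequences(builds, scaffolds)["Chr1"]
        assert seq.endswith(revcomp(scaffolds["B"]))

    def test_agp_rows_contiguous_and_exact(self):
        scaffolds, builds = self._two_scaffold_build()
        rows = builds["Chr1"].agp_rows
        assert [r.component_type for r in rows] == ["W", "U", "W"]
        pos = 0
        for r in rows:
            assert r.obj_beg == pos + 1
            pos = r.obj_end
            if r.component_type == "W":
                sid, beg, end, _ = r.fields
                assert end - beg + 1 == len(scaffolds[sid])
            else:
                assert r.fields[0] == 100 and r.obj_end - r.obj_beg + 1 == 100
        assert pos == builds["Chr1"].length

    def test_missing_scaffold_sequence_is_hard_error(self):
        with pytest.raises(KeyError):
            anchor.build_pseudochromosomes({1: [("nope", "+")]}, {})

    def test_deterministic_agp_output(self, tmp_path, study):
        result = study["anchoring"]
        p1, p2 = tmp_path / "a.agp", tmp_path / "b.agp"
        anchor.write_agp(result.builds, p1)
        anchor.write_agp(result.builds, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestLiftover:
    def test_identity_for_forward_first_scaffold(self):
        scaffolds = {"A": "ACGT" * 250}
        builds = anchor.build_pseudochromosomes({1: [("A", "+")]}, scaffolds)
        assert anchor.liftover(builds, "A", 10, 20, "+") == ("Chr1", 10, 20, "+")

    def test_minus_scaffold_mirrors_coordinates(self):
        scaffolds = {"A": "ACGTA" * 200}  # length 1000
        builds = anchor.build_pseudochromosomes({1: [("A", "-")]}, scaffolds)
        lifted = anchor.liftover(builds, "A", 1, 10, "+")
        assert lifted == ("Chr1", 991, 1000, "-")
        # the lifted interval spells the feature's reverse complement
        chrom = anchor.build_sequences(builds, scaffolds)["Chr1"]
        assert chrom[990:1000] == revcomp(scaffolds["A"][0:10])

    def test_unanchored_scaffold_is_unplaced(self):
        builds = anchor.build_pseudochromosomes({1: [("A", "+")]}, {"A": "ACGT" * 50})
        assert anchor.liftover(builds, "Z", 1, 10) is None

    def test_out_of_bounds_feature_rejected(self):
        builds = anchor.build_pseudochromosomes({1: [("A", "+")]}, {"A": "ACGT" * 50})
        with pytest.raises(ValueError):
            anchor.liftover(builds, "A", 100, 300)

    def test_round_trip_sequence_identity_for_all_planted_genes(self, study):
        truth, result = study["truth"], study["anchoring"]
        chrom_seqs = anchor.build_sequences(result.builds, truth.scaffolds)
        n_checked = 0
        for g in truth.gene_placements:
            lifted = anchor.liftover(result.builds, g.scaffold_id, g.start, g.end,
                                     g.strand)
            if lifted is None:
                continue
            chrom, start, end, strand = lifted
            seg = chrom_seqs[chrom][start - 1 : end]
            if strand == "-":
                seg = revcomp(seg)
            assert seg == study["cds"][g.gene_id]
            n_checked += 1
        assert n_checked > 0


class TestRecovery:
    def test_noiseless_map_recovers_order_and_orientation(self):
        # 2 linkage groups x 8 scaffolds x 3 markers, no cM jitter
        for seed in (21, 22, 23):
            t = synthetic.gen_genome(seed=seed, n_chromosomes=2,
                                     chromosome_length=80_000)
            synthetic.fragment_to_scaffolds(t, 8, seed=seed)
            df, flanks = synthetic.gen_linkage_map(t, 3, seed=seed)
            markers = [
                anchor.Marker(r.marker_id, int(r.linkage_group), float(r.cM),
                              flanks[r.flank_id])
                for r in df.itertuples()
            ]
            result = anchor.anchor_pipeline(markers, t.scaffolds)
            ev = synthetic.evaluate_anchoring(t, result.builds)
            assert ev["order_accuracy"] == 1.0
            assert ev["orientation_accuracy"] == 1.0

    def test_single_marker_scaffolds_stay_unplaced(self):
        t = synthetic.gen_genome(seed=31, n_chromosomes=1,
                                 chromosome_length=40_000)
        synthetic.fragment_to_scaffolds(t, 4, seed=31)
        df, flanks = synthetic.gen_linkage_map(t, 1, seed=31)
        markers = [
            anchor.Marker(r.marker_id, int(r.linkage_group), float(r.cM),
                          flanks[r.flank_id])
            for r in df.itertuples()
        ]
        result = anchor.anchor_pipeline(markers, t.scaffolds)
        assert result.report["n_scaffolds_anchored"] == 0
        assert sorted(result.unplaced_scaffolds) == sorted(t.scaffolds)

    def test_jittered_map_keeps_most_adjacencies(self):
        # uniform +-0.5 cM noise on a 1 cM / 250 kb map; scaffolds are
        # ~500 kb (the realistic scale for such maps: ~2 cM apart), so
        # adjacency accuracy across seeds stays >= 90%
        good = total = 0
        for seed in (41, 42, 43, 44, 45):
            t = synthetic.gen_genome(seed=seed, n_chromosomes=2,
                                     chromosome_length=2_500_000)
            synthetic.fragment_to_scaffolds(t, 5, seed=seed,
                                            min_length=100_000)
            df, flanks = synthetic.gen_linkage_map(t, 3, seed=seed, jitter_cM=0.5)
            markers = [
                anchor.Marker(r.marker_id, int(r.linkage_group), float(r.cM),
                              flanks[r.flank_id])
                for r in df.itertuples()
            ]
            result = anchor.anchor_pipeline(markers, t.scaffolds)
            true_next = {}
            lg_of = {c: i + 1 for i, c in enumerate(t.chromosomes)}
            by_chrom = {}
            for rec in t.scaffold_layout:
                by_chrom.setdefault(lg_of[rec.chromosome_id], []).append(rec)
            for lg, recs in by_chrom.items():
                recs.sort(key=lambda r: r.order_index)
                for a, b in zip(recs, recs[1:]):
                    true_next[a.scaffold_id] = b.scaffold_id
            for build in result.builds.values():
                ids = [sid for sid, _ in build.components]
                for a, b in zip(ids, ids[1:]):
                    total += 1
                    good += true_next.get(a) == b
        assert good / total >= 0.9
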