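"""Reference-database construction: screening, curation, profiles, packages."""

import numpy as np
import pytest

from microdiv import phylo, refdb, simdata
from microdiv.align import Alignment
from microdiv.util import encode_protein, rng_for


@pytest.fixture(scope="module")
def universe():
    cfg = simdata.UniverseConfig(n_phyla=2, genera_per_phylum=2, genomes_per_genus=2,
                                 n_markers=3, marker_len=60, focal_clades=2, seed=4)
    return simdata.simulate_universe(cfg)


@pytest.fixture(scope="module")
def train_profiles(universe):
    profiles = {}
    for m in range(1, 4):
        seqs = {g.genome_id: universe.marker_truth[(g.genome_id, m)]
                for g in universe.genomes}
        profiles[m] = refdb.build_profiles(Alignment.from_sequences(seqs), marker_id=m)
    return profiles


class TestProfiles:
    def test_pure_column_log_odds_closed_form(self):
        aln = Alignment.from_sequences({f"s{i}": "AAAA" for i in range(5)})
        prof = refdb.build_profiles(aln, pseudocount=1e-9)
        # 100% alanine vs uniform background: log2(1 / (1/20)) = log2(20)
        assert np.allclose(prof.log_odds[:, 0], np.log2(20), atol=1e-6)

    def test_uniform_column_log_odds_zero(self):
        seqs = {f"s{i}": simdata.decode_protein([i]) * 3 for i in range(20)}
        aln = Alignment.from_sequences(seqs)
        prof = refdb.build_profiles(aln, pseudocount=1e-9)
        assert np.allclose(prof.log_odds, 0.0, atol=1e-6)

    def test_training_sequence_beats_its_shuffles(self, universe, train_profiles):
        prof = train_profiles[1]
        seq = encode_protein(universe.marker_truth[(universe.genome_ids[0], 1)])
        base = refdb.score_profile(prof, seq)
        rng = rng_for(0, "shuffle")
        for _ in range(100):
            assert refdb.score_profile(prof, rng.permutation(seq)) <= base


class TestScreening:
    def test_intact_genomes_retained_with_full_hit_sets(self, universe, train_profiles):
        hits, discarded = refdb.screen_markers(universe.genomes, train_profiles)
        assert not discarded
        per_genome = {}
        for h in hits:
            per_genome.setdefault(h.genome_id, set()).add(h.marker_id)
        assert all(v == {1, 2, 3} for v in per_genome.values())

    def test_missing_marker_discards_genome(self, universe, train_profiles):
        victim = universe.genomes[0]
        g = refdb.GenomeRecord(victim.genome_id,
                               [p for i, p in enumerate(victim.proteins) if i != 1],
                               victim.taxonomy)
        _hits, discarded = refdb.screen_markers([g], train_profiles)
        assert victim.genome_id in discarded
        assert any("missing marker 2" in r for r in discarded[victim.genome_id])

    def test_duplicated_marker_discards_genome(self, universe, train_profiles):
        victim = universe.genomes[0]
        dup = victim.proteins[2]
        g = refdb.GenomeRecord(victim.genome_id,
                               victim.proteins + [(dup[0] + "_copy", dup[1])],
                               victim.taxonomy)
        _hits, discarded = refdb.screen_markers([g], train_profiles)
        assert any("not single-copy" in r for r in discarded[victim.genome_id])

    def test_empty_genome_list_rejected(self, train_profiles):
        with pytest.raises(ValueError):
            refdb.screen_markers([], train_profiles)


class TestSubsampling:
    def mk(self, gid, complete=False, soil=False):
        return refdb.GenomeRecord(gid, [("g1", "MKVL")], ("p", "f", "genusX"),
                                  complete=complete, soil=soil)

    def test_preference_order(self):
        genomes = [self.mk("g1"), self.mk("g2", complete=True),
                   self.mk("g3", soil=True), self.mk("g4", complete=True, soil=True),
                   self.mk("g5", complete=True, soil=True)]
        out = refdb.subsample_genera(genomes, k=2)
        assert sorted(g.genome_id for g in out) == ["g4", "g5"]

    def test_single_genome_genus_kept(self):
        out = refdb.subsample_genera([self.mk("only")], k=2)
        assert len(out) == 1

    def test_tie_breaks_lexicographically(self):
        genomes = [self.mk("c"), self.mk("a"), self.mk("b")]
        out = refdb.subsample_genera(genomes, k=2)
        assert sorted(g.genome_id for g in out) == ["a", "b"]

    def test_idempotent(self):
        genomes = [self.mk(f"g{i}", complete=i % 2 == 0) for i in range(6)]
        once = refdb.subsample_genera(genomes, k=2)
        twice = refdb.subsample_genera(once, k=2)
        assert [g.genome_id for g in once] == [g.genome_id for g in twice]


class TestConcatenate:
    def test_widths_add(self):
        a = Alignment.from_sequences({"x": "MKVLITGAGQ", "y": "MKVLITGAGQ"})
        b = Alignment.from_sequences({"x": "ACDEFGHIKLMN", "y": "ACDEFGHIKLMN"})
        assert refdb.concatenate([a, b]).n_cols == 22

    def test_missing_genome_gets_gap_block(self):
        a = Alignment.from_sequences({"x": "MKVL", "y": "MKVL"})
        b = Alignment.from_sequences({"x": "ACDE"})
        sup = refdb.concatenate([a, b])
        row_y = sup.to_dict()["y"]
        assert row_y == "MKVL----"

    def test_single_alignment_identity(self):
        a = Alignment.from_sequences({"x": "MKVL", "y": "MRVL"})
        sup = refdb.concatenate([a])
        assert sup.to_dict() == a.to_dict()


class TestCuration:
    def _alignments_with_rogue(self, universe, rogue_div=0.0):
        """Marker alignments over 8 genomes; optionally plant a rogue."""
        out = {}
        for m in range(1, 4):
            seqs = {gid: universe.marker_truth[(gid, m)] for gid in universe.genome_ids}
            if rogue_div:
                rng = rng_for(99, "rogue", m)
                seqs["ROGUE"] = simdata.decode_protein(rng.integers(0, 20, size=60))
            out[m] = Alignment.from_sequences(seqs)
        return out

    def test_clean_set_unchanged_in_one_iteration(self, universe):
        alns = self._alignments_with_rogue(universe)
        kept, trees, log = refdb.curate_by_branch_length(alns, threshold=5.0)
        assert log == []
        assert set(kept) == set(universe.genome_ids)

    def test_planted_rogue_removed_and_tree_matches_rebuild(self, universe):
        alns = self._alignments_with_rogue(universe, rogue_div=20.0)
        kept, trees, log = refdb.curate_by_branch_length(alns, threshold=2.0)
        assert len(log) == 1 and log[0] == {"ROGUE"}
        clean = {m: Alignment([i for i in a.ids if i != "ROGUE"],
                              a.codes[[r for r, i in enumerate(a.ids) if i != "ROGUE"]])
                 for m, a in alns.items()}
        for m in alns:
            rebuilt = refdb.marker_tree(clean[m])
            assert trees[m].to_newick() == rebuilt.to_newick()

    def test_output_has_no_long_terminal_branches(self, universe):
        alns = self._alignments_with_rogue(universe, rogue_div=20.0)
        _kept, trees, _log = refdb.curate_by_branch_length(alns, threshold=2.0)
        for t in trees.values():
            assert all(l.length <= 2.0 for l in t.leaves())

    def test_refusal_when_too_few_genomes_would_remain(self):
        rng = rng_for(1, "few")
        seqs = {f"s{i}": simdata.decode_protein(rng.integers(0, 20, size=40))
                for i in range(3)}
        alns = {1: Alignment.from_sequences(seqs)}
        with pytest.raises(ValueError):
            refdb.curate_by_branch_length(alns, threshold=0.01)


class TestReferencePackage:
    @pytest.fixture()
    def package(self, universe):
        alns = {m: Alignment.from_sequences(
            {gid: universe.marker_truth[(gid, m)] for gid in universe.genome_ids})
            for m in range(1, 4)}
        trees = {m: refdb.marker_tree(a) for m, a in alns.items()}
        return refdb.build_reference_package(alns, trees, universe.taxonomy, seed=4)

    def test_save_load_round_trip(self, package, tmp_path):
        path = tmp_path / "pkg"
        package.save(str(path))
        back = refdb.ReferencePackage.load(str(path))
        assert set(back.markers) == set(package.markers)
        for m in package.markers:
            a, b = package.markers[m], back.markers[m]
            assert a.alignment.to_dict() == b.alignment.to_dict()
            assert a.tree.to_newick(edge_numbers=True) == b.tree.to_newick(edge_numbers=True)
            assert np.allclose(a.profile.log_odds, b.profile.log_odds, atol=1e-8)
        assert back.taxonomy == package.taxonomy

    def test_tampering_detected_with_file_name(self, package, tmp_path):
        path = tmp_path / "pkg"
        package.save(str(path))
        victim = path / "markers" / "m02" / "tree.nwk"
        victim.write_text("(a:1,b:1);\n")
        with pytest.raises(ValueError, match="m02/tree.nwk"):
            refdb.ReferencePackage.load(str(path))

    def test_manifest_lists_one_tree_per_marker(self, package, tmp_path):
        import json

        path = tmp_path / "pkg"
        package.save(str(path))
        manifest = json.loads((path / "manifest.json").read_text())
        trees = [f for f in manifest["files"] if f.endswith("tree.nwk")]
        assert len(trees) == len(package.markers)

    def test_edge_numbering_survives_round_trip(self, package, tmp_path):
        path = tmp_path / "pkg"
        package.save(str(path))
        back = refdb.ReferencePackage.load(str(path))
        for m in package.markers:
            orig = {e.edge_num: e.name for e in package.markers[m].tree.edges() if e.is_leaf}
            after = {e.edge_num: e.name for e in back.markers[m].tree.edges() if e.is_leaf}
            assert orig == after


class TestDistances:
    def test_pairwise_deletion_ignores_gapped_sites(self):
        aln = Alignment.from_sequences({"a": "MKVL--", "b": "MKIL--", "c": "MKVLAA"})
        D, ids = refdb.alignment_distances(aln)
        # a vs b compared over 4 shared sites with 1 difference
        i, j = ids.index("a"), ids.index("b")
        assert D[i, j] == pytest.approx(float(phylo.poisson_correct(0.25)))
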