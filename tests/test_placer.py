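"""Two-stage filtering, profile alignment, likelihood placement, jplace."""

import numpy as np
import pytest

from microdiv import placer, refdb
from microdiv.align import Alignment
from microdiv.util import decode_protein, rng_for


class TestStage1:
    def test_exact_substring_read_passes_easily(self, small_universe, small_build):
        u = small_universe
        gid = u.genome_ids[0]
        read = u.marker_truth[(gid, 1)][5:45]
        hit = small_build.database.search_read(
            placer.encode_protein(read))
        assert hit is not None
        marker, _score, evalue = hit
        assert marker == 1
        assert evalue < 1e-10

    def test_random_reads_rarely_pass(self, small_build):
        rng = rng_for(0, "stage1-decoys")
        passed = 0
        n = 1000
        for i in range(n):
            seq = decode_protein(rng.integers(0, 20, size=40))
            out = placer.stage1_search({f"d{i}": seq}, small_build.database,
                                       evalue_max=1e-5)
            passed += len(out)
        assert passed / n < 0.05

    def test_empty_database_warns_and_returns_nothing(self):
        db = placer.Stage1Database([], calibration={"lambda": 0.3, "K": 0.1})
        with pytest.warns(UserWarning):
            out = placer.stage1_search({"r": "MKVLITGAGQ"}, db)
        assert out == {}

    def test_non_residue_characters_rejected(self, small_build):
        with pytest.raises(ValueError):
            placer.stage1_search({"r": "MKVL*TG"}, small_build.database)

    def test_empty_read_set_rejected(self, small_build):
        with pytest.raises(ValueError):
            placer.stage1_search({}, small_build.database)


class TestStage2:
    def test_marker_reads_retained_shuffles_rejected(self, small_universe, small_build):
        u = small_universe
        rng = rng_for(1, "stage2")
        reads, shuffled = {}, {}
        for i in range(50):
            gid = u.genome_ids[int(rng.integers(len(u.genome_ids)))]
            m = int(rng.integers(1, 5))
            seq = u.marker_truth[(gid, m)]
            start = int(rng.integers(0, len(seq) - 40))
            r = seq[start : start + 40]
            reads[f"t{i}"] = r
            shuffled[f"s{i}"] = "".join(rng.permutation(list(r)))
        cands = placer.stage1_search({**reads, **shuffled}, small_build.database)
        hits = placer.stage2_profile_filter(cands, {**reads, **shuffled},
                                            small_build.package, seed=1)
        kept = {h.read_id for h in hits}
        assert set(reads) <= kept
        assert not any(r in kept for r in shuffled)

    def test_stage2_survivors_subset_of_stage1(self, small_run, small_build):
        reads, _truth, sr, _ba = small_run
        cands = placer.stage1_search(reads, small_build.database)
        stage2_ids = {h.read_id for h in sr.filter_hits}
        assert stage2_ids <= set(cands)
        assert sr.n_stage2 <= sr.n_stage1

    def test_unknown_marker_rejected(self, small_build):
        with pytest.raises(ValueError):
            placer.stage2_profile_filter({"r": (99, 1e-9)}, {"r": "MKVL"},
                                         small_build.package)


class TestAlignToProfile:
    def test_exact_segment_maps_to_its_columns(self, small_universe, small_build):
        u = small_universe
        pkg = small_build.package.markers[1]
        gid = pkg.alignment.ids[0]
        row = pkg.alignment.to_dict()[gid]
        read = row.replace("-", "")[10:40]
        aligned = placer.align_to_profile("r", read, pkg.profile)
        assert (aligned.col_map >= 0).all()
        assert list(aligned.col_map) == list(range(10, 40))

    def test_inserted_residue_recorded_as_insertion(self):
        rng = rng_for(3, "ins")
        base = decode_protein(rng.integers(0, 20, size=40))
        aln = Alignment.from_sequences({f"s{i}": base for i in range(4)})
        prof = refdb.build_profiles(aln, marker_id=1)
        read = base[:20] + "W" + base[20:]
        aligned = placer.align_to_profile("r", read, prof)
        assert (aligned.col_map == -1).sum() == 1
        kept = aligned.col_map[aligned.col_map >= 0]
        assert list(kept) == list(range(40))

    def test_unalign_round_trip(self, small_build):
        pkg = small_build.package.markers[2]
        row = pkg.alignment.row(0)
        read = row.replace("-", "")[5:35]
        aligned = placer.align_to_profile("r", read, pkg.profile)
        assert aligned.unalign() == read


class TestPlacement:
    def test_exact_leaf_segment_places_on_own_pendant_edge(self, small_build):
        pkg = small_build.package.markers[1]
        eng = small_build.engines[1]
        gid = pkg.alignment.ids[0]
        read = pkg.alignment.to_dict()[gid].replace("-", "")
        aligned = placer.align_to_profile("r", read, pkg.profile)
        pl = eng.place(aligned)
        leaf_edge = next(e.edge_num for e in pkg.tree.edges()
                         if e.is_leaf and e.name == gid)
        assert pl.records[0][0] == leaf_edge
        assert pl.records[0][2] > 0.5

    def test_symmetric_cherry_gets_equal_weight(self):
        # two identical leaves in a cherry: their pendant edges must receive
        # like-weight-ratios equal to within 1e-6
        rng = rng_for(5, "cherry")
        base = rng.integers(0, 20, size=60)
        other = base.copy()
        other[:20] = (other[:20] + 1 + rng.integers(0, 18, size=20)) % 20
        seqs = {"L1": decode_protein(base), "L2": decode_protein(base),
                "O1": decode_protein(other), "O2": decode_protein(other)}
        aln = Alignment.from_sequences(seqs)
        D, ids = refdb.alignment_distances(aln)
        D = D + 0.01 * (1 - np.eye(4))  # break exact-zero distances
        np.fill_diagonal(D, 0.0)
        tree = refdb.build_tree_nj(D, ids)
        prof = refdb.build_profiles(aln, marker_id=1)
        mp = refdb.MarkerPackage(1, aln, prof, tree)
        eng = placer.PlacementEngine(mp)
        aligned = placer.align_to_profile("r", decode_protein(base), prof)
        pl = eng.place(aligned)
        lwr = {e: w for e, _ll, w, _d, _p in pl.records}
        e1 = next(e.edge_num for e in tree.edges() if e.name == "L1")
        e2 = next(e.edge_num for e in tree.edges() if e.name == "L2")
        assert abs(lwr[e1] - lwr[e2]) < 1e-6

    def test_lwr_normalization_and_truncation(self, small_run):
        _reads, _truth, sr, _ba = small_run
        for pls in sr.placements.values():
            for pl in pls:
                w = [r[2] for r in pl.records]
                assert len(pl.records) <= 20
                assert sum(w) <= 1 + 1e-9
                assert all(0 <= x <= 1 for x in w)
                assert w == sorted(w, reverse=True)

    def test_lwr_sums_to_one_when_all_edges_kept(self, small_build):
        pkg = small_build.package.markers[1]
        eng = small_build.engines[1]
        read = pkg.alignment.row(0).replace("-", "")[:40]
        aligned = placer.align_to_profile("r", read, pkg.profile)
        pl = eng.place(aligned, max_keep=10_000)
        assert sum(r[2] for r in pl.records) == pytest.approx(1.0, abs=1e-9)


class TestBranchMass:
    def test_mass_totals_equal_read_counts(self, small_run):
        _reads, truth, sr, _ba = small_run
        for m, pls in sr.placements.items():
            mass = placer.accumulate_branch_mass(pls, small_build_edges(sr, m))
            assert mass.sum() == pytest.approx(len(pls), abs=1e-9)

    def test_empty_sample_warns(self):
        with pytest.warns(UserWarning):
            mass = placer.accumulate_branch_mass([], 5)
        assert mass.sum() == 0


def small_build_edges(sr, m):
    return max(max(r[0] for r in pl.records) for pl in sr.placements[m]) + 1


class TestJplace:
    def _random_placements(self, tree, n, seed=0):
        rng = rng_for(seed, "jplace")
        E = tree.n_edges()
        out = []
        for i in range(n):
            k = int(rng.integers(1, 8))
            edges = rng.choice(E, size=k, replace=False)
            w = rng.dirichlet(np.ones(k))
            recs = sorted(
                [(int(e), float(-200 * rng.random()), float(x),
                  float(rng.random()), float(5 * rng.random()))
                 for e, x in zip(edges, w)],
                key=lambda r: -r[2])
            out.append(placer.Placement(read_id=f"r{i:04d}", records=recs))
        return out

    def test_round_trip_lossless(self, tmp_path, small_build):
        tree = small_build.package.markers[1].tree
        pls = self._random_placements(tree, 1000)
        path = tmp_path / "x.jplace"
        placer.write_jplace(str(path), pls, tree)
        back, _tree = placer.read_jplace(str(path))
        assert len(back) == len(pls)
        for a, b in zip(pls, back):
            assert a.read_id == b.read_id
            for ra, rb in zip(a.records, b.records):
                assert ra[0] == rb[0]
                assert all(abs(x - y) < 1e-9 for x, y in zip(ra[1:], rb[1:]))

    def test_fields_array_conforms(self, tmp_path, small_build):
        import json

        tree = small_build.package.markers[1].tree
        path = tmp_path / "x.jplace"
        placer.write_jplace(str(path), self._random_placements(tree, 3), tree)
        doc = json.loads(path.read_text())
        assert doc["version"] == 3
        assert doc["fields"] == ["edge_num", "likelihood", "like_weight_ratio",
                                 "distal_length", "pendant_length"]

    def test_unknown_edge_rejected_with_read_name(self, tmp_path, small_build):
        import json

        tree = small_build.package.markers[1].tree
        path = tmp_path / "x.jplace"
        placer.write_jplace(str(path), self._random_placements(tree, 1), tree)
        doc = json.loads(path.read_text())
        doc["placements"][0]["p"][0][0] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="r0000"):
            placer.read_jplace(str(path))
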