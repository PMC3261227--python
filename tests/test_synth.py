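"""Synthetic contig generation: determinism, planted-truth recovery,
site degradation and ortholog-pair simulation."""

import json

import numpy as np
import pytest

import spsfinder as sf


@pytest.fixture(scope="module")
def small_bundle():
    spec = sf.PlantSpec(
        contig_id="t",
        length=3000,
        genes=(
            sf.GenePlan("g0", "+", ((1500, 2100),),
                        utr_boxes=(("Brd", 10), ("K", 40))),
        ),
        modules=(
            sf.ModulePlan("m0", "g0", upstream_distance=100, spacer=17,
                          aboxes=(-30,)),
        ),
    )
    rec, genes, truth = sf.generate_contig(spec, seed=11)
    return spec, str(rec.seq), genes, truth


class TestGenerateContig:
    def test_deterministic_under_fixed_seed(self, small_bundle):
        spec, seq, _, truth = small_bundle
        rec2, _, truth2 = sf.generate_contig(spec, seed=11)
        assert str(rec2.seq) == seq
        assert truth2.to_json() == truth.to_json()
        rec3, _, _ = sf.generate_contig(spec, seed=12)
        assert str(rec3.seq) != seq

    def test_planted_module_recovered_exactly(self, small_bundle):
        spec, seq, genes, truth = small_bundle
        scanned = sf.scan_contig(seq, "t", genes)
        assert len(scanned) == 1
        sm = scanned[0]
        p = truth.pairs[0]
        assert (sm.module.pair.start, sm.module.pair.end) == (p["start"], p["end"])
        assert sm.module.pair.spacer_bp == 17
        assert sm.module.module_class == "SPS+A"
        assert sm.module.a_boxes[0][1] == 30
        assert sm.assignment.gene_id == "g0"
        assert sm.assignment.distance_bp == 100
        assert (sm.module.y_upstream, sm.module.y_downstream) == ("T", "C")

    def test_planted_codons_present(self, small_bundle):
        _, seq, genes, _ = small_bundle
        g = genes[0]
        assert seq[g.start_codon_pos:g.start_codon_pos + 3] == "ATG"
        assert seq[g.stop_codon_end - 3:g.stop_codon_end] == "TAA"

    def test_gc_content_controls_background(self):
        spec = sf.PlantSpec("t", 20000, genes=(), modules=(), gc=0.60,
                            clean_background=False)
        rec, _, _ = sf.generate_contig(spec, seed=5)
        s = str(rec.seq)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.60) < 0.02

    def test_infeasible_packing_rejected(self):
        spec = sf.PlantSpec(
            "t", 3000,
            genes=(sf.GenePlan("g0", "+", ((1500, 2100),)),),
            # A box on the gene side would land inside the CDS
            modules=(sf.ModulePlan("m0", "g0", 30, 17, aboxes=(40,)),),
        )
        with pytest.raises(sf.PackingError, match="CDS"):
            sf.generate_contig(spec, seed=0)

    def test_truth_roundtrips_through_json(self, small_bundle, tmp_path):
        _, _, _, truth = small_bundle
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = sf.PlantedTruth.from_json(path)
        assert back.pair_keys() == truth.pair_keys()


class TestCleanBackground:
    @pytest.mark.parametrize("seed", range(10))
    def test_recall_one_and_no_false_modules(self, seed):
        spec = sf.random_plant_spec(np.random.default_rng(seed))
        rec, genes, truth = sf.generate_contig(spec, seed=1000 + seed)
        scanned = sf.scan_contig(str(rec.seq), spec.contig_id, genes)
        r = sf.evaluate_recovery(truth, [sm.module for sm in scanned])
        assert r["recall"] == 1.0
        assert r["n_false"] == 0

    def test_raw_background_keeps_spurious_hits(self):
        spec = sf.PlantSpec("t", 50_000, genes=(), modules=(), gc=0.5,
                            clean_background=False)
        rec, _, _ = sf.generate_contig(spec, seed=77)
        pat = sf.compile_pattern("TGTGAT", "K")
        assert len(sf.scan_both_strands(str(rec.seq), pat)) > 0


class TestDegradeSite:
    def test_deletion_removes_pair_from_scan(self, small_bundle):
        spec, seq, genes, truth = small_bundle
        sid = truth.sites[0]["id"]
        seq2, truth2 = sf.degrade_site(seq, truth, sid, ("delete", 3))
        assert truth2.pairs == []
        assert len(seq2) == len(seq) - 1
        scanned = sf.scan_contig(seq2, "t", genes)
        assert scanned == []

    def test_y_substitution_keeps_pair_and_flips_flag(self, small_bundle):
        spec, seq, genes, truth = small_bundle
        up_id = truth.pairs[0]["left_site"]  # plus-strand gene: left = upstream
        seq2, truth2 = sf.degrade_site(seq, truth, up_id, ("substitute", 0, "C"))
        p = truth2.pairs[0]
        assert p["y_upstream"] == "C" and p["y_canonical"] is False
        scanned = sf.scan_contig(seq2, "t", genes)
        assert len(scanned) == 1
        mod = scanned[0].module
        assert mod.y_upstream == "C" and mod.y_canonical is False

    def test_consensus_breaking_substitution_drops_site(self, small_bundle):
        _, seq, _, truth = small_bundle
        sid = truth.sites[0]["id"]
        seq2, truth2 = sf.degrade_site(seq, truth, sid, ("substitute", 1, "A"))
        assert truth2.pairs == []
        assert len(seq2) == len(seq)

    def test_noop_edit_rejected(self, small_bundle):
        _, seq, _, truth = small_bundle
        site = truth.sites[0]
        with pytest.raises(ValueError, match="no-op"):
            sf.degrade_site(seq, truth, site["id"],
                            ("substitute", 0, site["site_seq"][0]))

    def test_matching_preserving_deletion_rejected(self, small_bundle):
        _, seq, _, truth = small_bundle
        site = truth.sites[0]
        # force the base after the site (motif 3' end) to duplicate the
        # final A so deleting it slides an identical base in
        if site["strand"] == "+":
            pos = site["end"]
            seq2 = seq[:pos] + "A" + seq[pos + 1:]
        else:
            pos = site["start"] - 1
            seq2 = seq[:pos] + "T" + seq[pos + 1:]
        with pytest.raises(ValueError, match="still matching"):
            sf.degrade_site(seq2, truth, site["id"], ("delete", 7))

    def test_unknown_site_rejected(self, small_bundle):
        _, seq, _, truth = small_bundle
        with pytest.raises(ValueError, match="unknown site"):
            sf.degrade_site(seq, truth, "nope", ("delete", 0))


class TestOrthologPair:
    def test_zero_divergence_identical(self):
        spec = sf.random_plant_spec(np.random.default_rng(1))
        ra, _, _, rb, _, _ = sf.generate_ortholog_pair(spec, 0.0, seed=5)
        assert str(ra.seq) == str(rb.seq)

    def test_protected_boxes_identical_organization(self):
        spec = sf.random_plant_spec(np.random.default_rng(2))
        ra, ga, _, rb, gb, _ = sf.generate_ortholog_pair(
            spec, 0.10, seed=6, indel_rate=0.002
        )
        pa = sf.profile_utrs(str(ra.seq), ga, "a")
        pb = sf.profile_utrs(str(rb.seq), gb, "b")
        for gid in pa:
            cls = sf.compare_organization(pa[gid], pb[gid]).conservation_class
            assert cls in ("identical", "identical-empty")

    def test_truth_coordinates_track_indels(self):
        spec = sf.random_plant_spec(np.random.default_rng(3))
        _, _, ta, rb, _, tb = sf.generate_ortholog_pair(
            spec, 0.05, seed=7, indel_rate=0.005
        )
        b = str(rb.seq)
        suh = sf.compile_pattern("YGTGRGAA", "SuH")
        for site in tb.sites:
            window = b[site["start"]:site["end"]]
            oriented = (
                window if site["strand"] == "+"
                else sf.reverse_complement(window)
            )
            assert suh.matches(oriented)
        for p in tb.pairs:
            assert p["spacer"] == [q for q in ta.pairs if q["module"] == p["module"]][0]["spacer"]

    def test_divergence_bounds_checked(self):
        spec = sf.random_plant_spec(np.random.default_rng(4))
        with pytest.raises(ValueError):
            sf.generate_ortholog_pair(spec, 1.5, seed=0)
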