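"""Chain consolidation, clone identity strings, BCR inference, doublets."""

import numpy as np
import pandas as pd
import pytest

import airrtoolkit as atk
from airrtoolkit.clonal_clustering import levenshtein
from airrtoolkit.errors import (
    EmptyRepertoire,
    MixedReceptorError,
    UnknownColumn,
)
from airrtoolkit.repertoire_assembly import strip_allele


def _contig(barcode, locus, aa, nt, umis, v="V1", j="J1", productive=True,
            reads=None):
    return {
        "barcode": barcode, "contig_id": f"{barcode}_{locus}_{aa}",
        "locus": locus, "v_gene": v, "d_gene": "NA", "j_gene": j,
        "c_gene": "NA", "cdr3_aa": aa, "cdr3_nt": nt,
        "reads": reads if reads is not None else umis * 10, "umis": umis,
        "productive": productive, "sample_id": "s1",
    }


def test_strip_allele():
    assert strip_allele("TRBV2*01") == "TRBV2"
    assert strip_allele("NA") == "NA"


class TestConsolidateChains:
    def test_filter_multi_keeps_top_umi_chain(self):
        df = pd.DataFrame([
            _contig("c1", "TRA", "CAAAF", "AAA", umis=5),
            _contig("c1", "TRA", "CGGGF", "GGG", umis=9),
        ])
        slots = atk.consolidate_chains(df, filter_multi=True)
        assert len(slots) == 1
        assert slots["cdr3_aa"].iloc[0] == "CGGGF"
        assert slots["n_collapsed"].iloc[0] == 1

    def test_multi_chain_joined_in_umi_order(self):
        df = pd.DataFrame([
            _contig("c1", "TRA", "CAAAF", "AAA", umis=5),
            _contig("c1", "TRA", "CGGGF", "GGG", umis=9),
        ])
        slots = atk.consolidate_chains(df)
        assert slots["cdr3_aa"].iloc[0] == "CGGGF;CAAAF"
        assert slots["n_collapsed"].iloc[0] == 2

    def test_max_chains_per_slot_truncates(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", umis=3),
            _contig("c1", "TRB", "CCF", "CCC", umis=2),
            _contig("c1", "TRB", "CGF", "GGG", umis=1),
        ])
        slots = atk.consolidate_chains(df, max_chains_per_slot=2)
        assert slots["cdr3_aa"].iloc[0] == "CAF;CCF"

    def test_nonproductive_dropped_by_default(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", umis=3, productive=False),
        ])
        slots = atk.consolidate_chains(df)
        assert slots.empty

    def test_umi_tie_broken_by_reads_then_nt(self):
        df = pd.DataFrame([
            _contig("c1", "TRA", "CAAAF", "TTT", umis=5, reads=10),
            _contig("c1", "TRA", "CGGGF", "AAA", umis=5, reads=10),
        ])
        slots = atk.consolidate_chains(df)
        # identical umis and reads: lexicographically smaller nt first
        assert slots["cdr3_nt"].iloc[0] == "AAA;TTT"

    def test_gamma_delta_arbitration_keeps_higher_umi_pair(self):
        df = pd.DataFrame([
            _contig("c1", "TRA", "CAAAF", "AAA", umis=2),
            _contig("c1", "TRB", "CBBBF", "CCC", umis=2),
            _contig("c1", "TRG", "CGGGF", "GGG", umis=10),
            _contig("c1", "TRD", "CDDDF", "TTT", umis=10),
        ])
        slots = atk.consolidate_chains(df)
        assert set(slots["locus"]) == {"TRG", "TRD"}

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        rows = [
            _contig(f"c{rng.integers(5)}", "TRB", f"C{aa}F", nt, int(u))
            for aa, nt, u in zip("AGLMNPQ", ["AAA"] * 7, rng.integers(1, 9, 7))
        ]
        df = pd.DataFrame(rows)
        a = atk.consolidate_chains(df)
        b = atk.consolidate_chains(df.copy())
        pd.testing.assert_frame_equal(a, b)


class TestTcrClonotypes:
    def test_clone_id_scheme(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots)
        row = cells[cells["raw_barcode"] == "cellA"].iloc[0]
        assert row["CTaa"] == "CAVRF_CASSF"
        assert row["CTgene"] == "TRAV1.TRAJ3.TRAC_TRBV2.TRBD1.TRBJ4.TRBC1"
        assert row["CTstrict"] == row["CTgene"] + "_" + row["CTnt"]
        assert row["barcode"] == "s1_cellA"

    def test_missing_chain_renders_na(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots)
        row = cells[cells["raw_barcode"] == "cellC"].iloc[0]
        assert row["CTaa"] == "NA_CASSLGF"

    def test_remove_na_drops_unpaired(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots, remove_na=True)
        assert set(cells["raw_barcode"]) == {"cellA"}

    def test_every_barcode_appears_once(self, messy_tcr_repertoire):
        truth, contigs = messy_tcr_repertoire
        tcr = atk.filter_receptor(contigs, "tcr")
        slots = atk.consolidate_chains(tcr)
        cells = atk.build_tcr_clonotypes(slots)
        assert cells["raw_barcode"].is_unique
        assert set(cells["raw_barcode"]) == set(tcr["barcode"])

    def test_rejects_bcr_loci(self):
        df = pd.DataFrame([_contig("c1", "IGH", "CAF", "TTT", 3)])
        slots = atk.consolidate_chains(df)
        with pytest.raises(MixedReceptorError):
            atk.build_tcr_clonotypes(slots)

    def test_empty_raises(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", 3, productive=False)
        ])
        slots = atk.consolidate_chains(df)
        with pytest.raises(EmptyRepertoire):
            atk.build_tcr_clonotypes(slots)


def _bcr_cell(barcode, nt, v="IGHV1", j="IGHJ1", light=True):
    rows = [_contig(barcode, "IGH", "C" + "A" * (len(nt) // 3 - 2) + "F", nt,
                    9, v=v, j=j)]
    if light:
        rows.append(_contig(barcode, "IGK", "CLLLF", "CTGCTGCTG", 5,
                            v="IGKV1", j="IGKJ1"))
    return rows


class TestBcrInference:
    def test_identical_heavy_chains_share_clone(self):
        nt = "TGTGCTAGAGGGACTAGCTTT"
        df = pd.DataFrame(_bcr_cell("c1", nt) + _bcr_cell("c2", nt))
        cells = atk.infer_bcr_clonotypes(atk.consolidate_chains(df))
        strict = cells.set_index("raw_barcode")["CTstrict"]
        assert strict["c1"] == strict["c2"]
        assert strict["c1"].startswith("IGH.cluster.")

    def test_similarity_just_below_threshold_splits(self):
        # length 30, 6 substitutions: similarity 0.8 < 0.85
        a = "TGTGCTAGAGGGACTAGCTTTAAACCCGGG"
        b = "TGGGCTATAGGGCCTAGATTTACACCCTGG"
        assert levenshtein(a, b) == 6 and len(a) == 30
        df = pd.DataFrame(_bcr_cell("c1", a) + _bcr_cell("c2", b))
        cells = atk.infer_bcr_clonotypes(atk.consolidate_chains(df))
        strict = cells.set_index("raw_barcode")["CTstrict"]
        assert strict["c1"] != strict["c2"]

    def test_same_sequence_different_v_gene_splits(self):
        nt = "TGTGCTAGAGGGACTAGCTTT"
        df = pd.DataFrame(
            _bcr_cell("c1", nt, v="IGHV1") + _bcr_cell("c2", nt, v="IGHV2")
        )
        cells = atk.infer_bcr_clonotypes(atk.consolidate_chains(df))
        strict = cells.set_index("raw_barcode")["CTstrict"]
        assert strict["c1"] != strict["c2"]

    def test_light_only_cell_falls_back(self):
        df = pd.DataFrame(
            [_contig("c1", "IGK", "CLLLF", "CTGCTGCTG", 5, v="IGKV1", j="IGKJ1")]
        )
        cells = atk.infer_bcr_clonotypes(atk.consolidate_chains(df))
        assert cells["CTstrict"].iloc[0].startswith("NA_IGKV1.IGKJ1")

    def test_matches_brute_force_components(self):
        """Inferred heavy-clone partition equals an all-pairs DP oracle."""
        rng = np.random.default_rng(42)
        rows = []
        base = "TGTGCTAGAGGGACTAGCTTTAAACCCGGG"
        for i in range(60):
            nt = list(base)
            for p in rng.choice(len(nt), size=rng.integers(0, 8), replace=False):
                nt[p] = "ACGT"[rng.integers(4)]
            rows.extend(
                _bcr_cell(f"c{i}", "".join(nt), v=f"IGHV{rng.integers(1, 3)}",
                          light=False)
            )
        df = pd.DataFrame(rows)
        cells = atk.infer_bcr_clonotypes(atk.consolidate_chains(df))
        labels = cells.set_index("raw_barcode")["CTstrict"]

        # oracle: all-pairs similarity + union-find
        seqs = df.set_index("barcode")["cdr3_nt"]
        vg = df.set_index("barcode")["v_gene"]
        bcs = list(seqs.index)
        parent = {b: b for b in bcs}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, a in enumerate(bcs):
            for b in bcs[i + 1:]:
                if vg[a] != vg[b]:
                    continue
                sim = 1 - levenshtein(seqs[a], seqs[b]) / max(
                    len(seqs[a]), len(seqs[b])
                )
                if sim >= 0.85:
                    parent[find(a)] = find(b)
        oracle = {b: find(b) for b in bcs}
        # same partition up to label permutation
        for a in bcs:
            for b in bcs:
                assert (labels[a] == labels[b]) == (oracle[a] == oracle[b])


class TestDoublets:
    def test_planted_doublets_recovered(self, messy_tcr_repertoire):
        truth, contigs = messy_tcr_repertoire
        flagged = atk.detect_doublets(contigs)
        assert sorted(flagged["barcode"]) == sorted(truth.doublet_barcodes)

    def test_tcr_and_bcr_required(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", 3),
            _contig("c1", "IGH", "CCF", "CCC", 2),
            _contig("c2", "TRA", "CAF", "TTT", 3),
            _contig("c2", "TRB", "CCF", "CCC", 2),
        ])
        flagged = atk.detect_doublets(df)
        assert list(flagged["barcode"]) == ["c1"]
        assert flagged["n_tcr"].iloc[0] == 1 and flagged["n_bcr"].iloc[0] == 1

    def test_nonproductive_other_receptor_not_flagged(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", 3),
            _contig("c1", "IGH", "CCF", "CCC", 2, productive=False),
        ])
        assert atk.detect_doublets(df).empty

    def test_symmetric_under_receptor_relabeling(self):
        df = pd.DataFrame([
            _contig("c1", "TRB", "CAF", "TTT", 3),
            _contig("c1", "IGH", "CCF", "CCC", 2),
        ])
        swapped = df.copy()
        swapped["locus"] = swapped["locus"].map({"TRB": "IGH", "IGH": "TRB"})
        a = atk.detect_doublets(df)
        b = atk.detect_doublets(swapped)
        assert len(a) == len(b) == 1
        assert a["n_tcr"].iloc[0] == b["n_bcr"].iloc[0]


class TestResolveCloneIds:
    def test_builtin_modes(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots)
        aa = atk.resolve_clone_ids(cells, "aa")
        assert aa[cells["raw_barcode"] == "cellA"].iloc[0] == "CAVRF_CASSF"
        for mode, col in [("gene", "CTgene"), ("nt", "CTnt"),
                          ("strict", "CTstrict")]:
            assert (atk.resolve_clone_ids(cells, mode) == cells[col]).all()

    def test_custom_metadata_column(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots)
        meta = pd.DataFrame(
            {"barcode": cells["barcode"], "external_clone": ["x", "y", "x"]}
        )
        got = atk.resolve_clone_ids(cells, "external_clone", meta)
        assert list(got) == ["x", "y", "x"]

    def test_unknown_column_raises(self, tiny_contigs):
        slots = atk.consolidate_chains(tiny_contigs)
        cells = atk.build_tcr_clonotypes(slots)
        with pytest.raises(UnknownColumn):
            atk.resolve_clone_ids(cells, "nope")
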