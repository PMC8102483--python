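import numpy as np
import pandas as pd
import pytest

from scskin.io import LRDatabase
from scskin.lr import (export_chord, export_sankey, score_interactions,
                       select_ligands, select_receptors, select_top)

from conftest import make_cm


def de_table(rows):
    """rows: (cluster, gene, log2fc, fdr)"""
    df = pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "fdr"])
    df["p_value"] = df["fdr"]
    df["direction"] = np.where((df.fdr < 0.05) & (df.log2fc > 0), "up",
                               np.where((df.fdr < 0.05) & (df.log2fc < 0),
                                        "down", "ns"))
    return df


class TestSelectLigands:
    def test_upregulated_intersection_only(self):
        db = LRDatabase([("L1", "R1"), ("L2", "R2")])
        de = de_table([
            ("A", "L1", 2.0, 0.001),     # upregulated ligand
            ("A", "NOTLIG", 3.0, 0.001),  # upregulated but not in db
            ("A", "L2", -1.0, 0.001),    # downregulated
            ("B", "L2", 1.0, 0.5),       # not significant
        ])
        sets = select_ligands(de, db)
        assert sets["A"] == {"L1"}
        assert sets["B"] == set()


class TestSelectReceptors:
    def make_inputs(self):
        # receiver cluster B: R1 expressed broadly, R2 rarely, R3 downregulated
        dense = np.zeros((4, 20), dtype=int)
        dense[0, :] = 3                     # R1 everywhere
        dense[1, 0] = 1                     # R2 in 1 of 10 B cells (5%)
        dense[2, :] = 2                     # R3 everywhere but downregulated
        dense[3, :] = 4                     # L1 ligand everywhere
        cm = make_cm(dense, genes=["R1", "R2", "R3", "L1"])
        labels = np.array(["A"] * 10 + ["B"] * 10)
        db = LRDatabase([("L1", "R1"), ("L1", "R2"), ("L1", "R3")])
        de = de_table([("B", "R3", -2.0, 0.001)])
        return cm, labels, db, de

    def test_constant_receptor_included(self):
        cm, labels, db, de = self.make_inputs()
        sets = select_receptors(cm, labels, de, db)
        assert "R1" in sets["B"]

    def test_rare_receptor_excluded_by_expr_frac(self):
        cm, labels, db, de = self.make_inputs()
        sets = select_receptors(cm, labels, de, db)
        assert "R2" not in sets["B"]

    def test_downregulated_receptor_excluded(self):
        cm, labels, db, de = self.make_inputs()
        sets = select_receptors(cm, labels, de, db)
        assert "R3" not in sets["B"]


class TestScoreInteractions:
    def hand_toy(self):
        # sender A expresses 4 ligands (2 upregulated), receiver B all
        # 4 receptors eligible, 5th pair's ligand never expressed
        genes = ["L1", "L2", "L3", "L4", "L5", "R1", "R2", "R3", "R4", "R5"]
        dense = np.zeros((10, 20), dtype=int)
        for i in range(4):
            dense[i, :10] = 2        # L1-4 in sender A
        for i in range(5, 10):
            dense[i, 10:] = 2        # R1-5 in receiver B
        cm = make_cm(dense, genes=genes)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        db = LRDatabase([(f"L{i}", f"R{i}") for i in range(1, 6)])
        ligand_sets = {"A": {"L1", "L2"}, "B": set()}
        receptor_sets = {"A": set(), "B": {"R1", "R2", "R3", "R4", "R5"}}
        return cm, labels, db, ligand_sets, receptor_sets

    def test_hand_enumerated_ratio(self):
        cm, labels, db, ligs, recs = self.hand_toy()
        scores = score_interactions(ligs, recs, cm, labels, db)
        ab = [s for s in scores if s.sender == "A" and s.receiver == "B"][0]
        assert (ab.active_events, ab.total_events) == (2, 4)
        assert ab.ratio == 0.5

    def test_no_upregulated_ligands_ratio_zero(self):
        cm, labels, db, _, recs = self.hand_toy()
        scores = score_interactions({"A": set(), "B": set()}, recs,
                                    cm, labels, db)
        ab = [s for s in scores if s.sender == "A" and s.receiver == "B"][0]
        assert ab.ratio == 0.0

    def test_never_expressed_pair_changes_nothing(self):
        cm, labels, db, ligs, recs = self.hand_toy()
        base = score_interactions(ligs, recs, cm, labels, db)
        db2 = LRDatabase(db.pairs + [("GHOSTL", "GHOSTR")])
        with_ghost = score_interactions(ligs, recs, cm, labels, db2)
        assert export_chord(base).equals(export_chord(with_ghost))

    def test_ratio_invariant_to_db_row_order(self):
        cm, labels, db, ligs, recs = self.hand_toy()
        rev = LRDatabase(list(reversed(db.pairs)))
        a = export_chord(score_interactions(ligs, recs, cm, labels, db))
        b = export_chord(score_interactions(ligs, recs, cm, labels, rev))
        assert a.equals(b)

    def test_planted_axis_attains_top_ratio(self):
        from scskin.simulate import (SimConfig, simulate_atlas,
                                     simulate_lr_database)
        from scskin.contrasts import differential_expression
        cfg = SimConfig(n_types=4, genes=1000, marker_genes_per_type=20,
                        de_genes_per_type=16, de_log2fc=2.5,
                        ligand_truth={0: 8},
                        cells_per_type_per_donor={"control": 25, "disease": 25},
                        seed=17)
        cm, meta, truth = simulate_atlas(cfg)
        db = LRDatabase(list(map(tuple, simulate_lr_database(
            truth, cm, n_background_pairs=10, seed=17).to_numpy())))
        labels = truth.true_type
        de = differential_expression(cm, labels, meta)
        ligs = select_ligands(de, db)
        recs = select_receptors(cm, labels, de, db, meta)
        scores = score_interactions(ligs, recs, cm, labels, db, meta)
        best = max(scores, key=lambda s: s.ratio)
        assert best.sender == "type0"
        kept, _ = select_top(scores, mode="fixed", fixed_cutoff=0.35)
        assert any(s.sender == "type0" for s in kept)
        assert best.ratio == max(s.ratio for s in kept)


class TestSelectTop:
    def fake_scores(self, ratios):
        from scskin.lr import InteractionScore
        return [InteractionScore(sender=f"s{i}", receiver="r",
                                 active_events=int(r * 100),
                                 total_events=100)
                for i, r in enumerate(ratios)]

    def test_fixed_cutoff_keeps_at_or_above(self):
        kept, cut = select_top(self.fake_scores([0.6, 0.5, 0.36, 0.34, 0.1]),
                               mode="fixed", fixed_cutoff=0.35)
        assert len(kept) == 3 and cut == 0.35

    def test_knee_cut_after_plateau(self):
        kept, cut = select_top(self.fake_scores([1.0, 0.9, 0.8, 0.1, 0.05]),
                               mode="knee")
        assert len(kept) == 3
        assert cut == pytest.approx(0.8)

    def test_all_equal_ratios_falls_back_to_fixed(self):
        with pytest.warns(UserWarning, match="knee undefined"):
            kept, cut = select_top(self.fake_scores([0.4, 0.4, 0.4]), mode="knee")
        assert cut == 0.35 and len(kept) == 3

    def test_fewer_than_three_scores_falls_back(self):
        with pytest.warns(UserWarning):
            kept, cut = select_top(self.fake_scores([0.9, 0.1]), mode="knee")
        assert cut == 0.35 and len(kept) == 1


class TestExports:
    def test_empty_scores_give_empty_tables(self):
        assert export_chord([]).empty and export_sankey([]).empty

    def test_one_pair_one_row_and_stable_ordering(self):
        from scskin.lr import InteractionScore
        s = InteractionScore(sender="B", receiver="A", active_events=1,
                             total_events=2, active_pairs=[("L", "R")])
        t = InteractionScore(sender="A", receiver="B", active_events=1,
                             total_events=2, active_pairs=[("L", "R")])
        chord = export_chord([s, t])
        assert chord.sender.tolist() == ["A", "B"]
        sankey = export_sankey([s, t])
        assert len(sankey) == 2
        assert sankey.iloc[0].tolist() == ["A", "B", "L", "R"]
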