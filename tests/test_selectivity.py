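"""Selectivity partition, receptor target scoring and network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netkit import selectivity
from netkit.selectivity import LigandReceptorMap
from netkit.simulate import (
    SimulationConfig,
    generate_lr_annotation_and_secretome,
    generate_pure_profiles,
)

from conftest import tiny_matrix, tiny_meta


def meta_one_per_type(types=("TU", "TAM", "TAT", "ADI", "MESO", "CAF"), n=2):
    rows = []
    for t in types:
        comp = "ascites" if t == "TAT" else "omentum"
        for j in range(n):
            rows.append((f"{t}{j}", t, comp, f"P{j}", False))
    return tiny_meta(rows)


def matrix_from_medians(medians, n=2):
    """Build a matrix whose per-type medians equal the given gene -> type map."""
    meta = meta_one_per_type(n=n)
    cols = {}
    for sample in meta.index:
        t = meta.loc[sample, "cell_type"]
        cols[sample] = {g: vals.get(t, 0.0) for g, vals in medians.items()}
    return pd.DataFrame(cols), meta


class TestCallExpressed:
    @pytest.mark.parametrize("median,expressed", [(2.0, False), (2.01, True)])
    def test_strict_boundary(self, median, expressed):
        m, meta = matrix_from_medians({"G": {"TU": median}})
        out = selectivity.call_expressed(m, meta)
        assert bool(out.loc["G", "TU"]) is expressed

    def test_unexpressed_gene_left_out_of_partition(self):
        m, meta = matrix_from_medians({"G": {"TU": 1.0}, "H": {"TU": 50.0}})
        calls, counts = selectivity.classify_selectivity(m, meta)
        assert counts["expressed"] == 1
        assert {c.gene for c in calls} == {"H"}


class TestClassifySelectivity:
    def test_single_stromal_type(self):
        medians = {"G": {"TU": 10.0, "TAM": 5.0, "TAT": 5.0,
                         "ADI": 8.0, "MESO": 9.0, "CAF": 100.0}}
        m, meta = matrix_from_medians(medians)
        calls, counts = selectivity.classify_selectivity(m, meta)
        call = calls[0]
        assert call.category == "host"
        assert call.host_category == "stroma"
        assert call.selective_types == frozenset({"CAF"})
        assert counts["stroma_combinations"] == {"CAF": 1}

    def test_shared_below_fold_change(self):
        medians = {"G": {"TU": 50.0, "CAF": 49.0}}
        m, meta = matrix_from_medians(medians)
        calls, counts = selectivity.classify_selectivity(m, meta)
        assert calls[0].category == "shared"

    def test_stroma_shared_three_ways(self):
        medians = {"G": {"TU": 5.0, "TAM": 4.0, "TAT": 3.0,
                         "ADI": 60.0, "MESO": 60.0, "CAF": 60.0}}
        m, meta = matrix_from_medians(medians)
        calls, counts = selectivity.classify_selectivity(m, meta)
        call = calls[0]
        assert call.host_category == "stroma"
        assert call.selective_types == frozenset({"ADI", "MESO", "CAF"})
        assert counts["stroma_combinations"] == {"ADI+CAF+MESO": 1}

    def test_tumour_selective(self):
        medians = {"G": {"TU": 100.0, "TAM": 3.0, "CAF": 2.0}}
        m, meta = matrix_from_medians(medians)
        calls, _ = selectivity.classify_selectivity(m, meta)
        assert calls[0].category == "tumour"

    def test_partition_is_complete(self, pure_cohort):
        matrix, meta, _ = pure_cohort
        calls, counts = selectivity.classify_selectivity(matrix, meta)
        assert counts["tumour"] + counts["host"] + counts["shared"] == counts["expressed"]
        assert len(calls) == counts["expressed"]
        assert sum(counts["host_split"].values()) == counts["host"]


class TestReceptorScores:
    def two_type_setup(self, r1, r2):
        medians = {"R1": r1, "R2": r2, "L": {"A": 0.0}}
        meta = tiny_meta([("a0", "TU", "omentum", "P0", False),
                          ("b0", "TAM", "omentum", "P0", False)])
        cols = {"a0": {g: v.get("A", 0.0) for g, v in medians.items()},
                "b0": {g: v.get("B", 0.0) for g, v in medians.items()}}
        matrix = pd.DataFrame(cols)
        lr_map = LigandReceptorMap({"L": frozenset({"R1", "R2"})})
        return lr_map, matrix, meta

    def test_worked_example_symmetric(self):
        lr_map, m, meta = self.two_type_setup({"A": 10.0, "B": 0.0},
                                              {"A": 0.0, "B": 10.0})
        scores = selectivity.receptor_target_scores(lr_map, m, meta)
        assert scores.loc["L", "TU"] == pytest.approx(1.0, abs=1e-12)
        assert scores.loc["L", "TAM"] == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_asymmetric(self):
        lr_map, m, meta = self.two_type_setup({"A": 10.0, "B": 10.0},
                                              {"A": 0.0, "B": 5.0})
        scores = selectivity.receptor_target_scores(lr_map, m, meta)
        assert scores.loc["L", "TU"] == pytest.approx(0.5, abs=1e-12)
        assert scores.loc["L", "TAM"] == pytest.approx(1.0, abs=1e-12)

    def test_single_receptor_single_type(self):
        lr_map, m, meta = self.two_type_setup({"A": 10.0, "B": 0.0},
                                              {"A": 0.0, "B": 0.0})
        lr_map = LigandReceptorMap({"L": frozenset({"R1"})})
        scores = selectivity.receptor_target_scores(lr_map, m, meta)
        assert scores.loc["L", "TU"] == 1.0
        assert scores.loc["L", "TAM"] == 0.0

    def test_absent_receptors_give_zero_row(self):
        lr_map, m, meta = self.two_type_setup({"A": 10.0, "B": 0.0},
                                              {"A": 0.0, "B": 10.0})
        lr_map = LigandReceptorMap({"L": frozenset({"MISSING"})})
        with pytest.warns(UserWarning, match="MISSING"):
            scores = selectivity.receptor_target_scores(lr_map, m, meta)
        assert (scores.loc["L"] == 0.0).all()

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_invariant_under_receptor_rescaling(self, seed, scale):
        """Scores are scale-free per receptor (step-i normalisation)."""
        rng = np.random.default_rng(seed)
        genes = [f"R{i}" for i in range(4)]
        meta = meta_one_per_type(n=1)
        base = pd.DataFrame(rng.uniform(0.0, 50.0, size=(4, len(meta))),
                            index=genes, columns=meta.index)
        lr_map = LigandReceptorMap({"L1": frozenset({"R0", "R1"}),
                                    "L2": frozenset({"R1", "R2", "R3"})})
        s1 = selectivity.receptor_target_scores(lr_map, base, meta)
        rescaled = base.copy()
        rescaled.loc["R1"] *= scale
        s2 = selectivity.receptor_target_scores(lr_map, rescaled, meta)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), rtol=1e-9, atol=1e-12)


class TestNetwork:
    def build(self, receptor_tu=5.0, flagged=True):
        medians = {
            "LIG": {"CAF": 100.0},
            "REC": {"TU": receptor_tu},
        }
        m, meta = matrix_from_medians(medians)
        flags = {"LIG": {"metastasis": flagged}}
        lr_map = LigandReceptorMap({"LIG": frozenset({"REC"})}, flags)
        calls, _ = selectivity.classify_selectivity(m, meta)
        return selectivity.build_metastasis_network(calls, lr_map, m, meta)

    def test_edge_emitted(self):
        edges = self.build()
        assert len(edges) == 1
        edge = edges.iloc[0]
        assert edge["ligand"] == "LIG"
        assert edge["source_cell_types"] == "CAF"
        assert edge["target_cell_type"] == "TU"

    def test_receptor_boundary_strict(self):
        assert len(self.build(receptor_tu=2.0)) == 0

    def test_unflagged_ligand_ignored(self):
        assert len(self.build(flagged=False)) == 0

    def test_planted_edges_recovered_exactly(self):
        """On generator output with planted single-target ligands, the edge
        list contains exactly the planted (ligand, producer, target) triples."""
        config = SimulationConfig(seed=9)
        profiles, markers = generate_pure_profiles(config)
        lr_map, _, truth = generate_lr_annotation_and_secretome(
            config, profiles, markers)
        meta = meta_one_per_type(n=2)
        cols = {s: profiles[meta.loc[s, "cell_type"]] for s in meta.index}
        matrix = pd.DataFrame(cols)
        calls, _ = selectivity.classify_selectivity(matrix, meta)
        edges = selectivity.build_metastasis_network(calls, lr_map, matrix, meta)
        got = {(e.ligand, e.source_cell_types, e.target_cell_type)
               for e in edges.itertuples()}
        want = {(lig, truth["producers"][lig], truth["targets"][lig])
                for lig in lr_map.ligands}
        assert got == want

    def test_score_max_at_planted_target(self):
        config = SimulationConfig(seed=9)
        profiles, markers = generate_pure_profiles(config)
        lr_map, _, truth = generate_lr_annotation_and_secretome(
            config, profiles, markers)
        meta = meta_one_per_type(n=2)
        matrix = pd.DataFrame({s: profiles[meta.loc[s, "cell_type"]]
                               for s in meta.index})
        scores = selectivity.receptor_target_scores(lr_map, matrix, meta)
        for ligand in lr_map.ligands:
            assert scores.loc[ligand].idxmax() == truth["targets"][ligand]
            assert scores.loc[ligand].max() == pytest.approx(1.0)


class TestLigandReceptorMap:
    def test_round_trip_tsv(self, tmp_path):
        lr_map = LigandReceptorMap(
            {"L1": frozenset({"R1", "R2"}), "L2": frozenset({"R2"})},
            {"L1": {"metastasis": True}})
        path = tmp_path / "lr.tsv"
        lr_map.to_frame().to_csv(path, sep="\t", index=False)
        loaded = LigandReceptorMap.from_tsv(path)
        assert loaded.receptors_by_ligand == lr_map.receptors_by_ligand
        assert loaded.flagged("metastasis") == ["L1"]

    def test_empty_receptor_set_rejected(self):
        with pytest.raises(ValueError):
            LigandReceptorMap({"L1": frozenset()})
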